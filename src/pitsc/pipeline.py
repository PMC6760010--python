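"""End-to-end pipeline driver.

Stage order is fixed: read and merge inputs, normalize, then per sex —
per-sex gene thresholds, exclusion and tiered marker classification, QC
filters within classified types, HVG/PCA with the permutation count of
significant PCs, kNN imputation of unclassified cells, doublet detection
and removal — then pooled over the cleaned cells: final gene thresholds,
percent-expressing tables, type-level DE with dominant/specific calls
(including the PIT and HPC group targets), sex DE, the cell-cycle
iteration, and an optional 2-D embedding.  Every stage logs cell counts,
and a manifest records parameters, derived seeds, and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import celltype, cellcycle, diffexp, dimred, doublets, qc, threshold
from .io import CountMatrix, read_tenx, normalize

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "stage_seed"]

log = logging.getLogger("pitsc")


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


@dataclass
class PipelineConfig:
    input_dirs: list[str] = field(default_factory=list)
    output_dir: str = "pitsc_out"
    seed: int = 0
    qc_fmt_sd_k: float = 2.0
    qc_tail: float = 0.015
    hvg_n_top: int = 1000
    hvg_min_cells: int = 30
    n_pc: int = 50
    pc_n_reps: int = 100
    knn_k: int = 30
    doublets_enabled: bool = True
    doublet_rate: float = 0.30
    doublet_k: int = 30
    doublet_alpha: float = 0.01
    doublet_reps: int = 10
    de_alpha: float = 0.001
    de_min_pct: float = 20.0
    de_fold: float = 3.0
    de_delta_pct: float = 30.0
    de_spec_pct: float = 5.0
    cycle_alpha: float = 0.001
    cycle_max_iter: int = 20
    cycle_seed_genes: str | None = None
    go_mitotic_genes: str | None = None
    embed_enabled: bool = False
    embed_perplexity: float = 40.0
    embed_n_iter: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class RunReport:
    manifest: dict
    output_dir: Path
    classification: pd.DataFrame
    dominance: diffexp.DominanceCall | None = None
    sex_dominance: diffexp.DominanceCall | None = None
    cycle: cellcycle.CycleState | None = None
    de: diffexp.DETestResult | None = None


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["outputs"][path.name] = _checksum(path)


CONCRETE = tuple(t for t in celltype.DEFAULT_MARKERS if t != "HPC")


def _is_typed(label: np.ndarray) -> np.ndarray:
    return np.array(
        [
            not (l in (celltype.AMBIGUOUS, celltype.UNCLASSIFIED) or l.startswith("excluded:"))
            for l in label
        ]
    )


def run_pipeline(
    config: PipelineConfig,
    matrix: CountMatrix | None = None,
    rules: celltype.RuleSet | None = None,
) -> RunReport:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": asdict(config),
        "seeds": {},
        "stages": {},
        "outputs": {},
    }
    rules = rules or celltype.default_ruleset()

    if matrix is None:
        log.info("stage=read inputs=%s", config.input_dirs)
        matrix = read_tenx(config.input_dirs)
    if "sex" not in matrix.cell_meta.columns:
        raise ValueError("cell metadata must provide a 'sex' column")
    sex = matrix.cell_meta["sex"].to_numpy()
    n0 = matrix.n_cells
    manifest["stages"]["input"] = {"cells": int(n0), "genes": int(matrix.n_genes)}

    norm = normalize(matrix)
    log.info("stage=normalize median_total=%.1f", norm.median_total)

    label = np.array([celltype.UNCLASSIFIED] * n0, dtype=object)
    provenance = np.array(["rule"] * n0, dtype=object)
    qc_reason = np.array(["kept"] * n0, dtype=object)
    doublet_flag = np.zeros(n0, dtype=bool)
    kept = np.ones(n0, dtype=bool)
    n_significant: dict[str, int] = {}

    for s in pd.unique(sex):
        sidx = np.flatnonzero(sex == s)
        sub_norm = norm.subset_cells(sidx)
        calls = threshold.expression_calls(sub_norm, source=f"sex:{s}")
        cls = celltype.classify_cells(calls, matrix.gene_symbols, rules)
        label[sidx] = cls.label
        log.info("stage=classify sex=%s counts=%s", s, dict(cls.counts()))

        excl = np.array([l.startswith("excluded:") for l in cls.label])
        kept[sidx[excl]] = False

        typed = _is_typed(cls.label)
        t_idx = sidx[typed]
        metrics = qc.qc_metrics(matrix.subset_cells(t_idx))
        report = qc.filter_cells(
            metrics, cls.label[typed], fmt_sd_k=config.qc_fmt_sd_k, tail=config.qc_tail
        )
        qc_reason[t_idx] = report.excluded["reason"].to_numpy()
        kept[t_idx[~report.kept_mask]] = False
        log.info(
            "stage=qc sex=%s excluded=%d", s, int((~report.kept_mask).sum())
        )

        live = sidx[kept[sidx]]
        sub_norm = norm.subset_cells(live)
        hvg = dimred.select_hvg(
            sub_norm, n_top=config.hvg_n_top, min_cells=config.hvg_min_cells
        )
        pcs = dimred.reduce(sub_norm, hvg, n_pc=config.n_pc)
        pcs.n_significant = dimred.n_significant_pcs(
            matrix.subset_cells(live),
            hvg,
            n_pc=config.n_pc,
            n_reps=config.pc_n_reps,
            seed=stage_seed(config.seed, f"pcs:{s}"),
            observed=pcs,
        )
        n_significant[str(s)] = pcs.n_significant
        log.info("stage=dimred sex=%s n_significant=%d", s, pcs.n_significant)

        live_cls = celltype.Classification(label=label[live], provenance=provenance[live])
        imputed = celltype.impute_labels(
            pcs.significant_scores,
            live_cls,
            np.array([s] * live.size, dtype=object),
            k=min(config.knn_k, live.size - 1),
        )
        label[live] = imputed.label
        provenance[live] = imputed.provenance
        log.info(
            "stage=impute sex=%s rescued=%d", s, int((imputed.provenance == "imputed").sum())
        )

        if config.doublets_enabled:
            result = doublets.detect_doublets(
                matrix.subset_cells(live),
                boost_rate=config.doublet_rate,
                k=config.doublet_k,
                alpha=config.doublet_alpha,
                n_reps=config.doublet_reps,
                seed=stage_seed(config.seed, f"doublets:{s}"),
                n_pc=max(2, pcs.n_significant),
                hvg_n_top=config.hvg_n_top,
                hvg_min_cells=config.hvg_min_cells,
            )
            doublet_flag[live] = result.flagged
            kept[live[result.flagged]] = False
            log.info("stage=doublets sex=%s flagged=%d", s, int(result.flagged.sum()))

    final = kept & _is_typed(label)
    manifest["stages"]["per_sex"] = {
        "excluded_class": int(sum(l.startswith("excluded:") for l in label)),
        "qc_excluded": int((qc_reason != "kept").sum()),
        "doublets": int(doublet_flag.sum()),
        "ambiguous_or_unclassified_remaining": int((kept & ~_is_typed(label)).sum()),
        "final_cells": int(final.sum()),
        "n_significant_pcs": n_significant,
    }
    manifest["seeds"] = {
        st: stage_seed(config.seed, st)
        for st in ["pcs:F", "pcs:M", "doublets:F", "doublets:M", "embed"]
    }

    classification = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "sex": sex,
            "label": label,
            "provenance": provenance,
            "qc_reason": qc_reason,
            "doublet": doublet_flag,
            "final": final,
        }
    )
    _write(classification, outdir / "classification.tsv", manifest)

    fidx = np.flatnonzero(final)
    report = RunReport(manifest=manifest, output_dir=outdir, classification=classification)
    if fidx.size:
        pooled_norm = norm.subset_cells(fidx)
        pooled_calls = threshold.expression_calls(pooled_norm, source="final:pooled")
        thr_table = pd.DataFrame(
            {
                "gene_id": matrix.gene_ids,
                "symbol": matrix.gene_symbols,
                "threshold": pooled_calls.thresholds.threshold,
                "degenerate": pooled_calls.thresholds.degenerate,
            }
        )
        _write(thr_table, outdir / "gene_thresholds.tsv", manifest)

        flabels = label[fidx]
        pct = threshold.percent_expressing(pooled_calls, flabels, matrix.gene_symbols)
        _write(pct.reset_index(), outdir / "percent_expressing.tsv", manifest)

        de = diffexp.de_tests(pooled_norm, pooled_calls, flabels, alpha=config.de_alpha)
        dominance = diffexp.call_dominant_specific(
            de,
            min_pct=config.de_min_pct,
            fold=config.de_fold,
            delta_pct=config.de_delta_pct,
            spec_pct=config.de_spec_pct,
        )
        dom_frame = dominance.frame()
        dom_frame.insert(1, "gene", np.tile(matrix.gene_symbols, len(dominance.calls)))
        _write(dom_frame, outdir / "dominance.tsv", manifest)

        fsex = sex[fidx]
        if len(pd.unique(fsex)) == 2:
            sexdom = diffexp.sex_de(
                pooled_norm,
                pooled_calls,
                flabels,
                fsex,
                alpha=config.de_alpha,
                min_pct=config.de_min_pct,
                fold=config.de_fold,
                delta_pct=config.de_delta_pct,
                spec_pct=config.de_spec_pct,
            )
            sex_frame = sexdom.frame()
            if len(sex_frame):
                sex_frame.insert(
                    1, "gene", np.tile(matrix.gene_symbols, len(sexdom.calls))
                )
            _write(sex_frame, outdir / "sex_dominance.tsv", manifest)
            report.sex_dominance = sexdom

        seed_list = (
            cellcycle.load_gene_list(config.cycle_seed_genes)
            if config.cycle_seed_genes
            else cellcycle.packaged_gene_list("cycle_seed_genes")
        )
        go_list = (
            cellcycle.load_gene_list(config.go_mitotic_genes)
            if config.go_mitotic_genes
            else cellcycle.packaged_gene_list("go_mitotic_genes")
        )
        cycle = cellcycle.iterate_cycle_markers(
            pooled_calls,
            pooled_norm,
            matrix.gene_symbols,
            seed_list,
            go_list,
            alpha=config.cycle_alpha,
            max_iter=config.cycle_max_iter,
        )
        _write(pd.DataFrame({"marker": cycle.markers}), outdir / "cycle_markers.tsv", manifest)
        cycle_cells = pd.DataFrame(
            {
                "barcode": matrix.barcodes[fidx],
                "score": cycle.score,
                "proliferating": cycle.candidates,
            }
        )
        _write(cycle_cells, outdir / "cycle_cells.tsv", manifest)
        manifest["stages"]["cycle"] = {
            "n_markers": len(cycle.markers),
            "threshold": None if np.isnan(cycle.score_threshold) else cycle.score_threshold,
            "n_proliferating": int(cycle.candidates.sum()),
            "converged": bool(cycle.converged),
            "iterations": cycle.iteration,
        }

        if config.embed_enabled:
            hvg = dimred.select_hvg(
                pooled_norm, n_top=config.hvg_n_top, min_cells=config.hvg_min_cells
            )
            pcs = dimred.reduce(pooled_norm, hvg, n_pc=config.n_pc)
            try:
                emb = dimred.embed2d(
                    pcs,
                    perplexity=config.embed_perplexity,
                    n_iter=config.embed_n_iter,
                    seed=stage_seed(config.seed, "embed"),
                )
            except Exception as exc:  # embedding is strictly optional
                warnings.warn(f"embedding skipped: {exc}")
                emb = None
            if emb is not None:
                _write(
                    pd.DataFrame(
                        {"barcode": matrix.barcodes[fidx], "x": emb[:, 0], "y": emb[:, 1]}
                    ),
                    outdir / "embedding.tsv",
                    manifest,
                )

        report.de = de
        report.dominance = dominance
        report.cycle = cycle

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
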