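"""Validation scenarios: planted-truth recovery metrics for every stage.

Each function builds a synthetic dataset under the package's standard study
conditions, runs the corresponding pipeline stage from scratch, and scores
the result against the generator's ground truth.  The same scenarios back
the acceptance tests and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import celltype, cellcycle, diffexp, dimred, doublets, threshold
from .io import normalize
from .refextend import FeatureInterval, extend_three_prime
from .synthetic import (
    CYCLE_PROGRAM_GENES,
    SyntheticConfig,
    generate_dataset,
    pituitary_config,
)

__all__ = [
    "classification_recovery",
    "doublet_recovery",
    "dominance_recovery",
    "pc_significance",
    "cycle_recovery",
    "refextend_check",
    "noise_config",
    "programs_config",
]


def classification_recovery(seed: int = 2, cells_per_type: int = 300) -> dict:
    """Rule classification plus kNN imputation on the nine-type scenario
    (fold-20 markers, 5% ambient leakage).

    A small hormone-dim somatotroph subpopulation — full secretory program
    but near-ambient Gh1/Ghrhr — provides the rule-unclassifiable cells
    that the kNN imputation stage exists to rescue.
    """
    from .synthetic import DEFAULT_MARKERS

    config = pituitary_config(
        n_cells_per_type=cells_per_type // 2,
        marker_fold=20.0,
        ambient_fraction=0.05,
        doublet_rate=0.0,
        cycling_fraction=0.0,
        seed=seed,
    )
    sym = {s: i for i, s in enumerate(config.gene_symbols)}
    n_dim = max(5, cells_per_type // 20)
    config.marker_program = {
        **config.marker_program,
        "Sdim": {
            **{sym[g]: 20.0 for g in DEFAULT_MARKERS["HPC"]},
            **{sym[g]: 1.5 for g in DEFAULT_MARKERS["S"]},
        },
    }
    config.n_cells_per_type = {
        **config.n_cells_per_type, "Sdim": {"F": n_dim, "M": n_dim}
    }
    config.mito_fraction_params = {
        **config.mito_fraction_params, "Sdim": (0.05, 0.015)
    }
    matrix, truth = generate_dataset(config)
    truth.cells.loc[truth.cells["cell_type"] == "Sdim", "cell_type"] = "S"
    norm = normalize(matrix)
    sex = truth.cells["sex"].to_numpy()
    rules = celltype.default_ruleset()
    label = np.empty(matrix.n_cells, dtype=object)
    provenance = np.empty(matrix.n_cells, dtype=object)
    rule_label_all = np.empty(matrix.n_cells, dtype=object)
    flips = 0
    for s in ("F", "M"):
        idx = np.flatnonzero(sex == s)
        sub_norm = norm.subset_cells(idx)
        calls = threshold.expression_calls(sub_norm, source=f"sex:{s}")
        cls = celltype.classify_cells(calls, matrix.gene_symbols, rules)
        hvg = dimred.select_hvg(sub_norm, n_top=300)
        pcs = dimred.reduce(sub_norm, hvg, n_pc=20)
        pcs.n_significant = dimred.n_significant_pcs(
            matrix.subset_cells(idx), hvg, n_pc=20, n_reps=10, seed=seed, observed=pcs
        )
        imputed = celltype.impute_labels(
            pcs.significant_scores, cls, np.array([s] * idx.size, dtype=object)
        )
        rule_typed = cls.label != celltype.UNCLASSIFIED
        flips += int((imputed.label[rule_typed] != cls.label[rule_typed]).sum())
        rule_label_all[idx] = cls.label
        label[idx] = imputed.label
        provenance[idx] = imputed.provenance
    truth_types = truth.cell_type
    rule_accuracy = float((rule_label_all == truth_types).mean())
    n_unclassified_before = int((rule_label_all == celltype.UNCLASSIFIED).sum())
    n_unclassified_after = int((label == celltype.UNCLASSIFIED).sum())
    imputed_correct = (provenance == "imputed") & (label == truth_types)
    return {
        "n_cells": matrix.n_cells,
        "rule_accuracy_pct": 100.0 * rule_accuracy,
        "unclassified_before": n_unclassified_before,
        "unclassified_after": n_unclassified_after,
        "imputed_cells": int((provenance == "imputed").sum()),
        "imputed_correct": int(imputed_correct.sum()),
        "rule_label_flips": flips,
    }


def doublet_recovery(seed: int = 3, cells_per_type: int = 500, n_reps: int = 10) -> dict:
    """Detection of 2% planted heterotypic doublets between two
    well-separated types."""
    config = pituitary_config(
        n_cells_per_type={
            "E": {"F": cells_per_type // 2, "M": cells_per_type // 2},
            "S": {"F": cells_per_type // 2, "M": cells_per_type // 2},
        },
        doublet_rate=0.02,
        cycling_fraction=0.0,
        seed=seed,
    )
    matrix, truth = generate_dataset(config)
    result = doublets.detect_doublets(
        matrix, n_reps=n_reps, seed=seed, hvg_n_top=300
    )
    planted = truth.is_doublet
    return {
        "n_cells": matrix.n_cells,
        "flagged_pct": 100.0 * float(result.flagged.mean()),
        "recall_pct": 100.0 * float(result.flagged[planted].mean()),
        "singlet_fpr_pct": 100.0 * float(result.flagged[~planted].mean()),
    }


def dominance_config(
    seed: int, n_types: int = 4, cells_per_type: int = 300, n_null: int = 2000,
    fold: float = 5.0, markers_per_type: int = 50,
) -> SyntheticConfig:
    n_planted = n_types * markers_per_type
    types = [f"T{i}" for i in range(n_types)]
    program = {
        t: {i * markers_per_type + g: fold for g in range(markers_per_type)}
        for i, t in enumerate(types)
    }
    return SyntheticConfig(
        n_genes=n_planted + n_null,
        n_cells_per_type={
            t: {"F": cells_per_type // 2, "M": cells_per_type // 2} for t in types
        },
        marker_program=program,
        baseline_mean_override={g: 0.5 for g in range(n_planted)},
        ambient_fraction=0.05,
        mito_gene_count=0,
        doublet_rate=0.0,
        seed=seed,
    )


def dominance_recovery(seed: int = 4, **kw) -> dict:
    """Dominant/specific calling with 50 planted fold-5 dominant genes per
    type over a sea of null genes."""
    config = dominance_config(seed, **kw)
    matrix, truth = generate_dataset(config)
    norm = normalize(matrix)
    calls = threshold.expression_calls(norm)
    de = diffexp.de_tests(norm, calls, truth.cell_type)
    dom = diffexp.call_dominant_specific(de, targets=list(de.types))
    roles = truth.genes["role"].to_numpy()
    null = roles == "baseline"
    recovered = 0
    planted_total = 0
    null_dominant = np.zeros(matrix.n_genes, dtype=bool)
    inclusion_ok = True
    for t, frame in dom.calls.items():
        mine = roles == f"marker:{t}"
        planted_total += int(mine.sum())
        recovered += int(frame["dominant"].to_numpy()[mine].sum())
        null_dominant |= frame["dominant"].to_numpy() & null
        inclusion_ok &= not (frame["specific"] & ~frame["dominant"]).any()
        inclusion_ok &= not (frame["dominant"] & ~frame["upregulated"]).any()
    return {
        "n_genes": matrix.n_genes,
        "planted": planted_total,
        "recovered_pct": 100.0 * recovered / planted_total,
        "null_dominant_pct": 100.0 * float(null_dominant[null].mean()),
        "inclusion_holds": bool(inclusion_ok),
    }


def noise_config(seed: int, n_genes: int = 300, n_cells: int = 400) -> SyntheticConfig:
    """No cell structure: one type, constant library size, Poisson limit."""
    return SyntheticConfig(
        n_genes=n_genes,
        n_cells_per_type={"A": {"F": n_cells // 2, "M": n_cells - n_cells // 2}},
        marker_program={},
        library_size_log_params=(0.0, 0.0),
        nb_dispersion=1e6,
        ambient_fraction=0.0,
        mito_gene_count=0,
        doublet_rate=0.0,
        seed=seed,
    )


def programs_config(seed: int = 0, fold: float = 10.0, n_cells: int = 150) -> SyntheticConfig:
    """Three disjoint 20-gene programs over a background type: three
    independent structure dimensions."""
    return SyntheticConfig(
        n_genes=300,
        n_cells_per_type={t: {"F": n_cells // 2, "M": n_cells // 2} for t in "ABCD"},
        marker_program={
            "A": {g: fold for g in range(20)},
            "B": {g: fold for g in range(20, 40)},
            "C": {g: fold for g in range(40, 60)},
        },
        baseline_mean_override={g: 0.5 for g in range(60)},
        library_size_log_params=(0.0, 0.0),
        ambient_fraction=0.0,
        mito_gene_count=0,
        doublet_rate=0.0,
        seed=seed,
    )


def pc_significance(seed: int = 0, n_seeds: int = 20, n_reps: int = 20) -> dict:
    """Permutation test calibration: pure noise vs three planted programs."""
    zero = 0
    for k in range(n_seeds):
        matrix, _ = generate_dataset(noise_config(seed + k))
        norm = normalize(matrix)
        hvg = dimred.select_hvg(norm, n_top=200, min_cells=10)
        zero += (
            dimred.n_significant_pcs(matrix, hvg, n_pc=10, n_reps=n_reps, seed=seed + k)
            == 0
        )
    matrix, _ = generate_dataset(programs_config(seed))
    norm = normalize(matrix)
    hvg = dimred.select_hvg(norm, n_top=200, min_cells=10)
    planted = dimred.n_significant_pcs(matrix, hvg, n_pc=20, n_reps=n_reps, seed=seed)
    return {
        "n_seeds": n_seeds,
        "noise_zero_pct": 100.0 * zero / n_seeds,
        "planted_n_significant": int(planted),
    }


def cycle_recovery(seed: int = 5, cells_per_type: int = 150) -> dict:
    """Iterative mitotic-marker refinement against a planted 40-gene
    program in 2% of cells, seeded with 10 genes."""
    config = pituitary_config(
        n_cells_per_type=cells_per_type, seed=seed, doublet_rate=0.0, cycling_fraction=0.02
    )
    matrix, truth = generate_dataset(config)
    norm = normalize(matrix)
    calls = threshold.expression_calls(norm)
    state = cellcycle.iterate_cycle_markers(
        calls,
        norm,
        matrix.gene_symbols,
        cellcycle.packaged_gene_list("cycle_seed_genes"),
        cellcycle.packaged_gene_list("go_mitotic_genes"),
    )
    cycling = truth.is_cycling
    return {
        "n_cells": matrix.n_cells,
        "converged": bool(state.converged),
        "iterations": int(state.iteration),
        "sensitivity_pct": 100.0 * float(state.candidates[cycling].mean()),
        "specificity_pct": 100.0 * float(1.0 - state.candidates[~cycling].mean()),
        "marker_recall_pct": 100.0
        * float(np.mean([g in state.markers for g in CYCLE_PROGRAM_GENES])),
        "markers_in_go": bool(
            set(state.markers) <= set(cellcycle.packaged_gene_list("go_mitotic_genes"))
        ),
    }


def refextend_toy_genome(seed: int = 0, n_genes: int = 60) -> list[FeatureInterval]:
    rng = np.random.default_rng(seed)
    genes = []
    pos = 1
    for i in range(n_genes):
        length = int(rng.integers(200, 3000))
        gap = int(rng.integers(0, 12000))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = "1" if i < 2 * n_genes // 3 else "2"
        genes.append(
            FeatureInterval(
                chrom=chrom, start=pos, end=pos + length, strand=strand,
                gene_id=f"g{i}", feature_kind="gene",
            )
        )
        pos += length + gap + 1
    return genes


def refextend_check(seed: int = 0, cap: int = 4000) -> dict:
    """Extension-rule agreement with an exhaustive nearest-feature scan,
    plus a global overlap sweep."""
    genes = refextend_toy_genome(seed)
    out, report = extend_three_prime(genes, cap=cap)
    rep = report.set_index("gene_id")
    agree = 0
    for g in genes:
        best = None
        for h in genes:
            if h is g or h.chrom != g.chrom:
                continue
            for b in (h.start, h.end):
                if g.strand == "+" and b > g.end:
                    gap = b - g.end - 1
                elif g.strand == "-" and b < g.start:
                    gap = g.start - b - 1
                else:
                    continue
                best = gap if best is None else min(best, gap)
        expected = cap if best is None else min(cap, max(best, 0) // 2)
        if g.strand == "-":
            expected = min(expected, g.start - 1)
        agree += int(rep.loc[g.gene_id, "extension"] == expected)
    overlaps = 0
    by_chrom: dict[str, list] = {}
    for f in out:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for spans in by_chrom.values():
        spans.sort()
        overlaps += sum(e1 >= s2 for (s1, e1), (s2, e2) in zip(spans, spans[1:]))
    anchored = extend_three_prime(
        [
            FeatureInterval("1", 100, 1000, "+", "a"),
            FeatureInterval("1", 11000, 12000, "+", "b"),
        ],
        cap=cap,
    )[1]
    return {
        "n_genes": len(genes),
        "rule_agreement_pct": 100.0 * agree / len(genes),
        "post_extension_overlaps": int(overlaps),
        "cap_limited_extension_bp": int(
            anchored.set_index("gene_id").loc["a", "extension"]
        ),
    }
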