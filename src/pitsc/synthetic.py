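"""Synthetic 10x-style UMI count matrices with known ground truth.

The generator emulates the structure of a dissociated-tissue droplet
experiment: multiple cell types defined by overlapping marker-gene
programs, log-normal library sizes, negative-binomial gene counts,
"ambient" leakage of highly expressed transcripts into every droplet
(the way growth-hormone mRNA shows up at low level in erythrocytes),
per-type mitochondrial count fractions, heterotypic doublets, a small
cycling subpopulation with a coherent mitotic program, and sex-dominant
genes in a subset of cell types.  Every planted property is returned as
ground truth so each pipeline stage can be scored against it.

Counts are sampled gene-wise negative-binomial (gamma-Poisson) with mean
``baseline x type-fold x library-scale``; ambient leakage binomially thins
each cell's own counts and replaces the removed mass with multinomial
draws from the pooled mean profile; mitochondrial counts are re-drawn so
each cell's mitochondrial fraction matches a truncated-normal draw;
doublets sum two singlet parents of distinct types and are downsampled
without replacement to the larger parent's library size — the same
generative form the doublet detector synthesizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CountMatrix, write_tenx

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "write_fixture",
    "pituitary_config",
    "DEFAULT_MARKERS",
    "CYCLE_PROGRAM_GENES",
]


class ConfigurationError(ValueError):
    pass


#: Marker-gene programs of the anterior pituitary cell types used by the
#: default classifier rules: erythrocytes (E), leukocytes (Le), endothelial
#: cells (EC), folliculostellate cells (FSC), the hormone-producing-cell
#: (HPC) common program, and the HPC subtypes C, G, T, S, L.
DEFAULT_MARKERS: dict[str, list[str]] = {
    "E": ["Hbb", "Hbb-b1", "Hba-a1", "Hba-a2"],
    "Le": ["Cd53", "Tyrobp", "Fcer1g", "Laptm5"],
    "EC": ["Plvap", "Emcn", "Clec14a", "Aplnr"],
    "FSC": ["S100b", "Fxyd1", "Gstm2", "Capn6"],
    "HPC": ["Resp18", "Uchl1", "Chgb", "Scg2"],
    "C": ["Pomc", "Crhr1", "Avpr1b"],
    "G": ["Cga", "Lhb", "Gnrhr", "Fshb"],
    "T": ["Cga", "Tshb", "Trhr"],
    "S": ["Gh1", "Ghrhr"],
    "L": ["Prl", "Agtr1b"],
}

CONTAMINANT_MARKERS: dict[str, list[str]] = {
    "pericyte": ["Col1a1", "Col1a3", "Dcn", "Lum"],
    "melanotroph": ["Pomc", "Pcsk2", "Pax7"],
    "posterior": ["Lhx2", "Nkx2-1", "Gfap", "S100b", "Avp", "Oxt"],
}

HPC_TYPES = ("C", "G", "T", "S", "L")

#: Canonical mitotic program used to name planted cycling genes.
CYCLE_PROGRAM_GENES: list[str] = [
    "Mki67", "Top2a", "Ccnb1", "Ccnb2", "Ccna2", "Cdk1", "Cdc20", "Plk1",
    "Aurka", "Aurkb", "Bub1", "Bub1b", "Birc5", "Cenpa", "Cenpe", "Cenpf",
    "Kif11", "Kif23", "Kif2c", "Kif20a", "Knl1", "Ndc80", "Nusap1", "Prc1",
    "Racgap1", "Spc25", "Tpx2", "Ube2c", "Anln", "Aspm", "Ccnf", "Cdca3",
    "Cdca8", "Ckap2", "Ect2", "Foxm1", "Hmmr", "Mad2l1", "Pbk", "Sgo1",
]

MITO_GENE_SYMBOLS = [
    "Mt-nd1", "Mt-nd2", "Mt-co1", "Mt-co2", "Mt-atp8", "Mt-atp6", "Mt-co3",
    "Mt-nd3", "Mt-nd4l", "Mt-nd4", "Mt-nd5", "Mt-nd6", "Mt-cyb",
]


@dataclass
class SyntheticConfig:
    n_genes: int
    n_cells_per_type: Mapping[str, Mapping[str, int]]  # type -> sex -> count
    marker_program: Mapping[str, Mapping[int, float]]  # type -> gene index -> fold
    baseline_mean_log_params: tuple[float, float] = (np.log(0.15), 1.0)
    baseline_mean_override: Mapping[int, float] = field(default_factory=dict)
    nb_dispersion: float = 10.0
    library_size_log_params: tuple[float, float] = (0.0, 0.35)
    ambient_fraction: float = 0.05
    mito_gene_count: int = 13
    mito_fraction_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    doublet_rate: float = 0.02
    cycling_fraction: float = 0.0
    cycle_program: Mapping[int, float] = field(default_factory=dict)
    sex_program: Mapping[tuple[str, str], Mapping[int, float]] = field(default_factory=dict)
    gene_symbols: list[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        total = sum(int(n) for by_sex in self.n_cells_per_type.values() for n in by_sex.values())
        if total <= 0:
            raise ConfigurationError("no cells requested")
        for prog in list(self.marker_program.values()) + [self.cycle_program] + list(
            self.sex_program.values()
        ):
            for g, f in prog.items():
                if not (0 <= g < self.n_genes):
                    raise ConfigurationError(f"gene index {g} out of range")
                if f < 1:
                    raise ConfigurationError("marker folds must be >= 1")
        for name, value in [
            ("ambient_fraction", self.ambient_fraction),
            ("doublet_rate", self.doublet_rate),
            ("cycling_fraction", self.cycling_fraction),
        ]:
            if not (0 <= value < 1):
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if self.mito_gene_count < 0 or self.mito_gene_count > self.n_genes:
            raise ConfigurationError("mito_gene_count out of range")


@dataclass
class GroundTruth:
    cells: pd.DataFrame  # barcode, cell_type, sex, replicate, is_doublet, parents, is_cycling
    genes: pd.DataFrame  # gene_id, symbol, role

    @property
    def cell_type(self) -> np.ndarray:
        return self.cells["cell_type"].to_numpy()

    @property
    def is_doublet(self) -> np.ndarray:
        return self.cells["is_doublet"].to_numpy()

    @property
    def is_cycling(self) -> np.ndarray:
        return self.cells["is_cycling"].to_numpy()


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["baseline", "assign", "sampling", "ambient", "mito", "doublets"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_dataset(config: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Sample a count matrix and its ground truth; deterministic given seed."""
    config.validate()
    rng = _streams(config.seed)
    n_genes = config.n_genes

    # per-gene baseline means
    loc, scale = config.baseline_mean_log_params
    baseline = rng["baseline"].lognormal(mean=loc, sigma=scale, size=n_genes)
    for g, m in config.baseline_mean_override.items():
        baseline[g] = m

    mito_idx = np.arange(n_genes - config.mito_gene_count, n_genes)
    is_mito = np.zeros(n_genes, dtype=bool)
    is_mito[mito_idx] = True

    # singlet roster
    types, sexes = [], []
    for t, by_sex in config.n_cells_per_type.items():
        for sex, n in by_sex.items():
            types += [t] * int(n)
            sexes += [sex] * int(n)
    types = np.array(types, dtype=object)
    sexes = np.array(sexes, dtype=object)
    n_singlets = len(types)
    order = rng["assign"].permutation(n_singlets)
    types, sexes = types[order], sexes[order]
    replicate = np.array(
        [f"{s}{1 + (i % 2)}" for i, s in enumerate(sexes)], dtype=object
    )

    n_cycling = int(round(config.cycling_fraction * n_singlets))
    cycling = np.zeros(n_singlets, dtype=bool)
    if n_cycling:
        cycling[rng["assign"].choice(n_singlets, size=n_cycling, replace=False)] = True

    # mean matrix: baseline x type fold x (cycle fold) x (sex fold) x library scale
    lib_loc, lib_scale = config.library_size_log_params
    libscale = rng["sampling"].lognormal(mean=lib_loc, sigma=lib_scale, size=n_singlets)
    mu = np.repeat(baseline[:, None], n_singlets, axis=1)
    for t, prog in config.marker_program.items():
        cols = np.flatnonzero(types == t)
        if cols.size == 0 or not prog:
            continue
        genes = np.fromiter(prog.keys(), dtype=int)
        folds = np.fromiter(prog.values(), dtype=float)
        mu[np.ix_(genes, cols)] *= folds[:, None]
    if config.cycle_program and n_cycling:
        genes = np.fromiter(config.cycle_program.keys(), dtype=int)
        folds = np.fromiter(config.cycle_program.values(), dtype=float)
        cols = np.flatnonzero(cycling)
        mu[np.ix_(genes, cols)] *= folds[:, None]
    for (t, sex), prog in config.sex_program.items():
        cols = np.flatnonzero((types == t) & (sexes == sex))
        if cols.size == 0 or not prog:
            continue
        genes = np.fromiter(prog.keys(), dtype=int)
        folds = np.fromiter(prog.values(), dtype=float)
        mu[np.ix_(genes, cols)] *= folds[:, None]
    mu *= libscale[None, :]

    # gamma-Poisson = negative binomial with inverse-dispersion r
    r = config.nb_dispersion
    lam = rng["sampling"].gamma(shape=r, scale=mu / r)
    counts = rng["sampling"].poisson(lam).astype(np.int64)

    # ambient leakage: thin each cell, replace removed mass from pooled profile
    a = config.ambient_fraction
    if a > 0:
        kept = rng["ambient"].binomial(counts, 1.0 - a)
        removed = counts.sum(axis=0) - kept.sum(axis=0)
        pooled = counts.sum(axis=1).astype(float)
        pooled_p = pooled / pooled.sum()
        for j in np.flatnonzero(removed > 0):
            kept[:, j] += rng["ambient"].multinomial(removed[j], pooled_p)
        counts = kept

    # mitochondrial rescaling to a planted per-cell fraction
    target_fmt = np.zeros(n_singlets)
    if config.mito_gene_count:
        mito_profile = baseline[mito_idx] / baseline[mito_idx].sum()
        for j in range(n_singlets):
            mean, sd = config.mito_fraction_params.get(types[j], (0.05, 0.02))
            f = float(np.clip(rng["mito"].normal(mean, sd), 0.0, 0.95))
            target_fmt[j] = f
            non_mito_total = counts[~is_mito, j].sum()
            m_star = int(round(f / (1.0 - f) * non_mito_total))
            counts[mito_idx, j] = rng["mito"].multinomial(m_star, mito_profile)

    # heterotypic doublets: sum two distinct-type same-sex parents, downsample
    n_doublets = int(round(config.doublet_rate * n_singlets))
    doublet_cols, parent_a, parent_b, doublet_sex = [], [], [], []
    for _ in range(n_doublets):
        while True:
            i, j = rng["doublets"].integers(0, n_singlets, size=2)
            if types[i] != types[j] and sexes[i] == sexes[j]:
                break
        summed = counts[:, i] + counts[:, j]
        target = max(counts[:, i].sum(), counts[:, j].sum())
        doublet_cols.append(
            rng["doublets"].multivariate_hypergeometric(summed, int(target))
        )
        parent_a.append(i)
        parent_b.append(j)
        doublet_sex.append(sexes[i])

    if n_doublets:
        counts = np.concatenate([counts, np.stack(doublet_cols, axis=1)], axis=1)

    n_cells = counts.shape[1]
    barcodes = np.array([f"CELL{k:05d}" for k in range(n_cells)], dtype=object)
    cell_type = np.concatenate([types, np.array(["doublet"] * n_doublets, dtype=object)])
    sex_all = np.concatenate([sexes, np.array(doublet_sex, dtype=object)])
    rep_all = np.concatenate(
        [replicate, np.array([f"{s}1" for s in doublet_sex], dtype=object)]
    )
    is_doublet = np.concatenate(
        [np.zeros(n_singlets, dtype=bool), np.ones(n_doublets, dtype=bool)]
    )
    cyc_all = np.concatenate([cycling, np.zeros(n_doublets, dtype=bool)])

    symbols = (
        np.array(config.gene_symbols, dtype=object)
        if config.gene_symbols is not None
        else np.array([f"Gene{i:05d}" for i in range(n_genes)], dtype=object)
    )
    gene_ids = np.array([f"SYN{i:05d}" for i in range(n_genes)], dtype=object)
    role = np.array(["baseline"] * n_genes, dtype=object)
    for t, prog in config.marker_program.items():
        for g in prog:
            role[g] = f"marker:{t}" if role[g] == "baseline" else role[g] + f"|marker:{t}"
    for g in config.cycle_program:
        role[g] = "cycle"
    for (t, sex), prog in config.sex_program.items():
        for g in prog:
            role[g] = f"sex:{t}:{sex}"
    role[mito_idx] = "mito"

    gene_meta = pd.DataFrame(
        {"chrom": np.where(is_mito, "MT", "1")}, index=pd.Index(gene_ids, name="gene_id")
    )
    cell_meta = pd.DataFrame(
        {"sex": sex_all, "replicate": rep_all},
        index=pd.Index(barcodes, name="barcode"),
    )
    matrix = CountMatrix(counts, gene_ids, symbols, barcodes, cell_meta, gene_meta)

    truth_cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "cell_type": cell_type,
            "sex": sex_all,
            "replicate": rep_all,
            "is_doublet": is_doublet,
            "parent_a": [""] * n_singlets + [barcodes[i] for i in parent_a],
            "parent_b": [""] * n_singlets + [barcodes[j] for j in parent_b],
            "is_cycling": cyc_all,
            "target_fmt": np.concatenate([target_fmt, np.full(n_doublets, np.nan)]),
        }
    )
    truth_genes = pd.DataFrame({"gene_id": gene_ids, "symbol": symbols, "role": role})
    return matrix, GroundTruth(cells=truth_cells, genes=truth_genes)


def write_fixture(
    matrix: CountMatrix, truth: GroundTruth, directory: Path | str, overwrite: bool = False
) -> Path:
    """Emit a 10x-layout directory plus ground-truth sidecar tables."""
    directory = Path(directory)
    write_tenx(matrix, directory, overwrite=overwrite)
    truth.cells.to_csv(directory / "truth_cells.tsv", sep="\t", index=False)
    truth.genes.to_csv(directory / "truth_genes.tsv", sep="\t", index=False)
    return directory


def pituitary_config(
    n_cells_per_type: int | Mapping[str, Mapping[str, int]] = 150,
    marker_fold: float = 30.0,
    marker_baseline: float = 1.0,
    ambient_fraction: float = 0.05,
    doublet_rate: float = 0.02,
    cycling_fraction: float = 0.02,
    cycle_fold: float = 60.0,
    sex_fold: float = 150.0,
    n_extra_genes: int = 400,
    include_contaminants: bool = False,
    seed: int = 0,
) -> SyntheticConfig:
    """Build the default pituitary-like scenario used throughout the tests.

    Nine (or twelve, with contaminant classes) cell types carry the default
    marker rules' genes; HPC subtypes additionally carry the common HPC
    program.  A 40-gene mitotic program is planted in a small cycling
    subpopulation, and a female program in lactotrophs plus a male program
    in gonadotrophs provide sex-dominant structure.  ``n_cells_per_type``
    may be a single integer (cells per type per sex) or the full map.

    The contaminant-class rule genes are always part of the gene universe;
    when the contaminant cell types themselves are not simulated those
    genes sit at trace abundance, the way transcripts of a dissected-away
    lobe appear in the remaining tissue.
    """
    marker_names: list[str] = []
    for genes in DEFAULT_MARKERS.values():
        for g in genes:
            if g not in marker_names:
                marker_names.append(g)
    contaminant_only = [
        g
        for genes in CONTAMINANT_MARKERS.values()
        for g in genes
        if g not in marker_names
    ]
    sex_genes = ["Cyp2c12", "Prlr-f1", "Sult1e1", "Eif2s3y", "Ddx3y", "Kdm5d"]
    symbols = (
        marker_names
        + contaminant_only
        + sex_genes
        + CYCLE_PROGRAM_GENES
        + [f"Gene{i:05d}" for i in range(n_extra_genes)]
        + MITO_GENE_SYMBOLS
    )
    index = {s: i for i, s in enumerate(symbols)}
    n_genes = len(symbols)

    def prog(names: list[str], fold: float) -> dict[int, float]:
        return {index[n]: fold for n in names}

    marker_program: dict[str, dict[int, float]] = {}
    for t in ("E", "Le", "EC", "FSC"):
        marker_program[t] = prog(DEFAULT_MARKERS[t], marker_fold)
    for t in HPC_TYPES:
        marker_program[t] = {
            **prog(DEFAULT_MARKERS["HPC"], marker_fold),
            **prog(DEFAULT_MARKERS[t], marker_fold),
        }
    if include_contaminants:
        for t, genes in CONTAMINANT_MARKERS.items():
            marker_program[t] = prog(genes, marker_fold)
        # melanotrophs share the secretory (HPC) program, as in tissue
        marker_program["melanotroph"].update(prog(DEFAULT_MARKERS["HPC"], marker_fold))

    type_names = list(marker_program)
    if isinstance(n_cells_per_type, int):
        n_main = n_cells_per_type
        n_cells = {
            t: {"F": n_main, "M": n_main}
            if t in DEFAULT_MARKERS or t == "HPC"
            else {"F": max(5, n_main // 10), "M": max(5, n_main // 10)}
            for t in type_names
        }
    else:
        n_cells = {t: dict(v) for t, v in n_cells_per_type.items()}

    override = {index[g]: marker_baseline for g in marker_names}
    # rule genes of absent contaminant classes: trace abundance only
    override.update(
        {index[g]: marker_baseline if include_contaminants else 0.002 for g in contaminant_only}
    )
    override.update({index[g]: 0.01 for g in sex_genes})
    override.update({index[g]: 0.04 for g in CYCLE_PROGRAM_GENES})

    sex_program = {
        ("L", "F"): prog(["Cyp2c12", "Prlr-f1", "Sult1e1"], sex_fold),
        ("G", "M"): prog(["Eif2s3y", "Ddx3y", "Kdm5d"], sex_fold),
    }
    mito_params = {t: (0.05 + 0.01 * (i % 3), 0.015) for i, t in enumerate(type_names)}

    return SyntheticConfig(
        n_genes=n_genes,
        n_cells_per_type=n_cells,
        marker_program=marker_program,
        baseline_mean_log_params=(np.log(0.3), 1.0),
        baseline_mean_override=override,
        ambient_fraction=ambient_fraction,
        mito_gene_count=len(MITO_GENE_SYMBOLS),
        mito_fraction_params=mito_params,
        doublet_rate=doublet_rate,
        cycling_fraction=cycling_fraction,
        cycle_program=prog(CYCLE_PROGRAM_GENES, cycle_fold),
        sex_program=sex_program,
        gene_symbols=symbols,
        seed=seed,
    )
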