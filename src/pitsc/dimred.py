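"""Highly variable gene selection, standardized/clamped PCA, and the
count-permutation test for the number of significant components.

Gene dispersion is phi = (s^2 - m) / m^2 on normalized counts (zero for a
Poisson-like gene); genes are binned into equal-frequency bins by mean and
phi is centered by the bin median and scaled by the bin MAD so that highly
variable genes can be ranked across the mean-expression range.  Log
expression of the selected genes is standardized per gene and clamped to
[-10, 10] before a truncated SVD, which caps the leverage of genes highly
expressed only in a small subpopulation.

The null for "how many PCs are real" shuffles each gene's UMI counts among
cells — preserving every gene's marginal count distribution while
destroying cell-wise correlation — and re-runs the identical transform;
observed singular values exceeding the maximum over all null repetitions
count as significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io import CountMatrix, NormalizedMatrix, normalize

__all__ = ["HVGStats", "PCSpace", "select_hvg", "reduce", "n_significant_pcs", "embed2d"]


@dataclass
class HVGStats:
    mean: np.ndarray
    variance: np.ndarray
    dispersion: np.ndarray
    bin: np.ndarray
    norm_dispersion: np.ndarray
    selected: np.ndarray  # bool per gene


@dataclass
class PCSpace:
    scores: np.ndarray  # cells x n_pc
    loadings: np.ndarray  # genes(selected, nonzero-sd) x n_pc
    singular_values: np.ndarray  # descending
    n_significant: int | None = None

    @property
    def significant_scores(self) -> np.ndarray:
        k = self.n_significant if self.n_significant else self.scores.shape[1]
        return self.scores[:, : max(k, 2)]


def select_hvg(
    norm: NormalizedMatrix,
    n_top: int = 1000,
    min_cells: int = 30,
    n_bins: int = 20,
) -> HVGStats:
    """Rank genes by within-bin normalized dispersion and select the top."""
    E = norm.E
    n_genes = E.shape[0]
    expressed_cells = (E > 0).sum(axis=1)
    eligible = expressed_cells >= min_cells
    m = E.mean(axis=1)
    s2 = E.var(axis=1, ddof=1) if E.shape[1] > 1 else np.zeros(n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, (s2 - m) / np.maximum(m, 1e-300) ** 2, np.nan)

    bins = np.full(n_genes, -1)
    norm_disp = np.full(n_genes, np.nan)
    idx = np.flatnonzero(eligible & (m > 0))
    if idx.size:
        order = np.argsort(m[idx], kind="stable")
        ranks = np.empty(idx.size, dtype=int)
        ranks[order] = np.arange(idx.size)
        bins[idx] = np.minimum(ranks * n_bins // idx.size, n_bins - 1)
        for b in range(n_bins):
            members = idx[bins[idx] == b]
            if members.size == 0:
                continue
            med = np.median(phi[members])
            mad = np.median(np.abs(phi[members] - med))
            if mad == 0:
                norm_disp[members] = 0.0
            else:
                norm_disp[members] = (phi[members] - med) / mad

    selected = np.zeros(n_genes, dtype=bool)
    ranked = idx[np.argsort(-norm_disp[idx], kind="stable")]
    if ranked.size < n_top:
        warnings.warn(f"only {ranked.size} eligible genes; selecting all")
    selected[ranked[:n_top]] = True
    return HVGStats(m, s2, phi, bins, norm_disp, selected)


def _standardize_clamp(log_expr: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Cells x genes matrix of per-gene standardized, clamped log expression."""
    X = log_expr[selected].T.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance selected genes")
    X = (X[:, keep] - mu[keep]) / sd[keep]
    return np.clip(X, -10.0, 10.0)


def _svd(X: np.ndarray, n_pc: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_pc = min(n_pc, min(X.shape) - 1)
    if n_pc >= min(X.shape) - 1 or min(X.shape) <= 200:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        return U[:, :n_pc], s[:n_pc], Vt[:n_pc]
    U, s, Vt = spla.svds(X, k=n_pc)
    order = np.argsort(-s)
    return U[:, order], s[order], Vt[order]


def reduce(norm: NormalizedMatrix, hvg: HVGStats, n_pc: int = 50) -> PCSpace:
    """Standardize-and-clamp the selected genes' log expression, then SVD."""
    if not hvg.selected.any():
        raise ValueError("no genes selected")
    X = _standardize_clamp(norm.log_expr, hvg.selected)
    U, s, Vt = _svd(X, n_pc)
    return PCSpace(scores=U * s, loadings=Vt.T, singular_values=s)


def permute_gene_counts(dense: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle each gene's counts among cells independently, preserving the
    gene-wise marginal count distributions exactly."""
    return rng.permuted(dense, axis=1)


def n_significant_pcs(
    matrix: CountMatrix,
    hvg: HVGStats,
    n_pc: int = 50,
    n_reps: int = 100,
    seed: int | np.random.Generator | None = 0,
    observed: PCSpace | None = None,
) -> int:
    """Count singular values above the max over gene-wise count permutations.

    The HVG set is frozen; each repetition permutes every gene's UMI counts
    among cells, renormalizes, and re-applies the standardize/clamp/SVD
    transform (standardization statistics recomputed on the permuted data),
    recording the top singular value.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if observed is None:
        observed = reduce(normalize(matrix), hvg, n_pc=n_pc)
    dense = np.asarray(matrix.counts.todense())
    null_max = np.empty(n_reps)
    for rep in range(n_reps):
        perm = permute_gene_counts(dense, rng)
        pm = CountMatrix(
            sp.csr_matrix(perm),
            matrix.gene_ids,
            matrix.gene_symbols,
            matrix.barcodes,
            matrix.cell_meta,
            matrix.gene_meta,
        )
        X = _standardize_clamp(normalize(pm).log_expr, hvg.selected)
        _, s, _ = _svd(X, 1)
        null_max[rep] = s[0]
    threshold = null_max.max()
    n_sig = int((observed.singular_values > threshold).sum())
    if n_sig == len(observed.singular_values):
        warnings.warn("all computed PCs significant; increase n_pc")
    return n_sig


def embed2d(
    pcs: PCSpace,
    perplexity: float = 40.0,
    n_iter: int = 2000,
    seed: int = 0,
    backend=None,
) -> np.ndarray | None:
    """2-D neighbor embedding of the significant PC scores (visualization only).

    Delegates to a pluggable backend (default: scikit-learn's t-SNE); when
    no backend is available the pipeline proceeds without an embedding.
    """
    X = pcs.significant_scores
    if X.shape[1] < 2:
        raise ValueError("need at least 2 significant PCs")
    if backend is None:
        try:
            from sklearn.manifold import TSNE
        except ImportError:  # pragma: no cover
            warnings.warn("no embedding backend available; skipping")
            return None
        perplexity = min(perplexity, (X.shape[0] - 1) / 3.0)
        backend = TSNE(
            n_components=2,
            perplexity=perplexity,
            max_iter=max(n_iter, 250),
            random_state=seed,
            init="pca",
        )
    return np.asarray(backend.fit_transform(X))
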