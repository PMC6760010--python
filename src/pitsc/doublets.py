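"""Synthetic-doublet boosting and kNN hypergeometric doublet detection.

Heterotypic doublets form hybrid expression profiles that cluster apart
from both parent types.  The detector boosts the data with 30% additional
synthetic doublets (random parent pairs drawn with replacement, counts
summed then downsampled without replacement to the larger parent's library
size), reduces the boosted matrix to PC space, and asks, for each true
cell, whether its 30 nearest neighbors contain more synthetic cells than a
hypergeometric draw would give.  P-values are BH-adjusted across true
cells, the run is repeated with fresh randomness, and the union of flagged
cells over repetitions is the final doublet set.  Homotypic doublets are
by construction nearly invisible to this test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import hypergeom
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, normalize
from .dimred import n_significant_pcs, reduce, select_hvg

__all__ = ["BoostSet", "DoubletResult", "synthesize_doublets", "detect_doublets"]


@dataclass
class BoostSet:
    parent_pairs: np.ndarray  # (n_synth, 2) cell indices
    synthetic_counts: sp.csr_matrix  # genes x n_synth
    boost_rate: float


@dataclass
class DoubletResult:
    synth_neighbor_count: np.ndarray  # per true cell, from the last repetition
    p_value: np.ndarray
    adj_p: np.ndarray
    flagged: np.ndarray  # union over repetitions
    n_reps: int
    per_rep_flags: np.ndarray | None = None  # reps x true cells


def synthesize_doublets(
    matrix: CountMatrix,
    boost_rate: float = 0.30,
    seed: int | np.random.Generator = 0,
) -> BoostSet:
    """Create ``round(boost_rate * n_cells)`` synthetic doublet columns."""
    if boost_rate <= 0:
        raise ValueError("boost_rate must be positive")
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_true = matrix.n_cells
    n_synth = int(round(boost_rate * n_true))
    dense = np.asarray(matrix.counts.todense())
    totals = dense.sum(axis=0)
    pairs = np.empty((n_synth, 2), dtype=int)
    cols = np.empty((matrix.n_genes, n_synth), dtype=np.int64)
    for s in range(n_synth):
        i, j = rng.integers(0, n_true, size=2)
        while j == i:
            j = rng.integers(0, n_true)
        pairs[s] = (i, j)
        summed = dense[:, i] + dense[:, j]
        target = int(max(totals[i], totals[j]))
        cols[:, s] = rng.multivariate_hypergeometric(summed, target)
    return BoostSet(
        parent_pairs=pairs, synthetic_counts=sp.csr_matrix(cols), boost_rate=boost_rate
    )


def detect_doublets(
    matrix: CountMatrix,
    boost_rate: float = 0.30,
    k: int = 30,
    alpha: float = 0.01,
    n_reps: int = 10,
    seed: int | np.random.Generator = 0,
    n_pc: int | None = None,
    hvg_n_top: int = 1000,
    hvg_min_cells: int = 30,
) -> DoubletResult:
    """Flag true cells whose PC-space neighborhoods are enriched for
    synthetic doublets.

    Each repetition redraws parent pairs, re-runs HVG selection and PCA on
    the boosted matrix, and tests each true cell's synthetic-neighbor count
    against Hypergeometric(population = n_true - 1 + n_synth, successes =
    n_synth, draws = k); self is excluded from the neighbor set.  Flags are
    the union of (BH-adjusted p < alpha) over repetitions.

    Neighbor distances must be measured in the informative subspace — noise
    components swamp the cluster separations otherwise — so when ``n_pc``
    is not given it is set to the permutation-test count of significant PCs
    of the unboosted matrix (minimum 2).
    """
    if matrix.n_cells < k + 1:
        raise ValueError("need more cells than neighbors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_pc is None:
        norm0 = normalize(matrix)
        hvg0 = select_hvg(norm0, n_top=hvg_n_top, min_cells=hvg_min_cells)
        cap = max(2, min(20, min(matrix.counts.shape) - 2))
        n_sig = n_significant_pcs(
            matrix, hvg0, n_pc=cap, n_reps=10, seed=rng,
            observed=reduce(norm0, hvg0, n_pc=cap),
        )
        n_pc = max(2, n_sig)
    n_true = matrix.n_cells
    flagged = np.zeros(n_true, dtype=bool)
    per_rep = np.zeros((n_reps, n_true), dtype=bool)
    s_count = p_val = adj = None
    for rep in range(n_reps):
        boost = synthesize_doublets(matrix, boost_rate, rng)
        n_synth = boost.synthetic_counts.shape[1]
        boosted = CountMatrix(
            sp.hstack([matrix.counts, boost.synthetic_counts], format="csr"),
            matrix.gene_ids,
            matrix.gene_symbols,
            np.concatenate(
                [matrix.barcodes, np.array([f"SYNTH{s}" for s in range(n_synth)], dtype=object)]
            ),
        )
        norm = normalize(boosted)
        hvg = select_hvg(norm, n_top=hvg_n_top, min_cells=hvg_min_cells)
        pcs = reduce(norm, hvg, n_pc=n_pc)
        if pcs.scores.shape[1] < 2:
            raise ValueError("degenerate PCA on boosted matrix")
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs.scores)
        _, nbr = nn.kneighbors(pcs.scores[:n_true])
        is_synth = nbr >= n_true
        not_self = nbr != np.arange(n_true)[:, None]
        s_count = np.empty(n_true, dtype=int)
        for i in range(n_true):
            keep = np.flatnonzero(not_self[i])[:k]
            s_count[i] = int(is_synth[i, keep].sum())
        p_val = hypergeom.sf(s_count - 1, n_true - 1 + n_synth, n_synth, k)
        adj = multipletests(p_val, method="fdr_bh")[1]
        per_rep[rep] = adj < alpha
        flagged |= per_rep[rep]
    return DoubletResult(
        synth_neighbor_count=s_count,
        p_value=p_val,
        adj_p=adj,
        flagged=flagged,
        n_reps=n_reps,
        per_rep_flags=per_rep,
    )
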