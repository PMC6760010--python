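"""Per-gene Otsu thresholds on log expression and the expressing/not calls.

Marker genes in droplet data leak at low levels into cell types that do not
express them (ambient contamination), so a simple nonzero test over-calls
expression.  Each gene's log10 expression distribution is instead split at
the threshold maximizing the between-class variance

    sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2,

computed over a 256-bin histogram on the gene's observed [min, max] range;
candidate thresholds are the bin left edges and a cell expresses the gene
when its log expression is >= the chosen threshold.  For unimodal
zero-inflated genes this deliberately under-calls the nonzero fraction; the
same convention is applied everywhere for consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NormalizedMatrix

__all__ = [
    "GeneThresholds",
    "ExpressionCalls",
    "otsu_threshold",
    "otsu_threshold_discrete",
    "expression_calls",
    "percent_expressing",
]


@dataclass
class GeneThresholds:
    threshold: np.ndarray  # per gene, NaN when degenerate
    degenerate: np.ndarray  # per gene bool (< 2 distinct values)
    n_bins: int = 256


@dataclass
class ExpressionCalls:
    calls: np.ndarray  # bool genes x cells
    thresholds: GeneThresholds
    source: str = ""


def _sigma_b2_from_cumulative(w0: np.ndarray, s0: np.ndarray, n: int, total: float) -> np.ndarray:
    """Between-class variance at each candidate from cumulative count/sum."""
    w1 = n - w0
    s1 = total - s0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / w0
        mu1 = s1 / w1
        sb2 = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
    sb2[(w0 == 0) | (w1 == 0)] = 0.0
    return sb2


def otsu_threshold(
    values: np.ndarray, n_bins: int = 256, return_curve: bool = False
) -> float | tuple[float, np.ndarray]:
    """Otsu threshold of a 1-D sample over an ``n_bins`` histogram.

    Candidates are the ``n_bins`` left bin edges (including the minimum);
    class 0 holds values strictly below the candidate, class 1 values >= it.
    Ties in sigma_B^2 resolve to the smallest candidate.  Returns NaN for
    samples with fewer than two distinct values.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty value vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    vmin, vmax = v.min(), v.max()
    if vmin == vmax:
        return (np.nan, np.zeros(n_bins)) if return_curve else np.nan
    edges = np.linspace(vmin, vmax, n_bins + 1)
    # bin k holds values in [edges[k], edges[k+1]); the max goes to the last bin
    idx = np.searchsorted(edges, v, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v, minlength=n_bins)
    # cumulative below each candidate edge k: bins 0..k-1
    w0 = np.concatenate(([0], np.cumsum(counts)))[:n_bins].astype(float)
    s0 = np.concatenate(([0.0], np.cumsum(sums)))[:n_bins]
    sb2 = _sigma_b2_from_cumulative(w0, s0, v.size, float(v.sum()))
    k = int(np.argmax(sb2))  # first occurrence = smallest candidate on ties
    thr = float(edges[k])
    return (thr, sb2) if return_curve else thr


def otsu_threshold_discrete(values: np.ndarray) -> float:
    """Otsu threshold for small-integer scores, one bin per observed value.

    Candidates are the sorted distinct values; classes split as < / >=.
    """
    v = np.asarray(values, dtype=float)
    uniq, counts = np.unique(v, return_counts=True)
    if uniq.size < 2:
        return np.nan
    sums = uniq * counts
    w0 = np.concatenate(([0], np.cumsum(counts)))[:-1].astype(float)
    s0 = np.concatenate(([0.0], np.cumsum(sums)))[:-1]
    sb2 = _sigma_b2_from_cumulative(w0, s0, v.size, float(sums.sum()))
    return float(uniq[int(np.argmax(sb2))])


def expression_calls(
    norm: NormalizedMatrix,
    cell_subset: np.ndarray | None = None,
    n_bins: int = 256,
    source: str = "",
) -> ExpressionCalls:
    """Compute per-gene thresholds on a cell subset and call all cells.

    Thresholds are fit on ``log_expr[:, cell_subset]``; the boolean call
    matrix covers every cell of ``norm`` with the >= convention.  Genes with
    fewer than two distinct values get no threshold: if their common value
    is 0 no cell is called, otherwise every cell at or above that value is.
    """
    L = norm.log_expr
    sub = L if cell_subset is None else L[:, np.asarray(cell_subset)]
    if sub.shape[1] == 0:
        raise ValueError("empty cell subset")
    n_genes = L.shape[0]
    thr = np.full(n_genes, np.nan)
    degen = np.zeros(n_genes, dtype=bool)
    effective = np.empty(n_genes)
    for i in range(n_genes):
        t = otsu_threshold(sub[i], n_bins=n_bins)
        if np.isnan(t):
            degen[i] = True
            common = sub[i, 0]
            effective[i] = np.inf if common == 0 else common
        else:
            thr[i] = t
            effective[i] = t
    calls = L >= effective[:, None]
    return ExpressionCalls(
        calls=calls, thresholds=GeneThresholds(thr, degen, n_bins), source=source
    )


def percent_expressing(
    calls: ExpressionCalls,
    labels: np.ndarray,
    gene_names: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percent of cells per type expressing each gene above threshold."""
    labels = np.asarray(labels)
    if labels.shape[0] != calls.calls.shape[1]:
        raise ValueError("labels do not match the call matrix")
    types = [t for t in pd.unique(labels)]
    cols = {}
    for t in types:
        mask = labels == t
        if mask.sum() == 0:  # pragma: no cover - unique() precludes this
            warnings.warn(f"type {t} has no cells; excluded")
            continue
        cols[t] = 100.0 * calls.calls[:, mask].mean(axis=1)
    index = None if gene_names is None else pd.Index(gene_names, name="gene")
    return pd.DataFrame(cols, index=index)
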