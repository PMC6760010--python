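"""Per-cell QC metrics and cell-type-stratified exclusion rules.

Damaged cells leak cytoplasmic RNA and retain mitochondrial transcripts, so
a high mitochondrial count fraction (f_MT) marks them; its distribution
differs between cell types, which is why the cut is taken per type at
mean + k*sd rather than globally.  Count-depth outliers (genes per cell and
total UMI per cell) are likewise trimmed per type at both tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["QCMetrics", "QCReport", "qc_metrics", "filter_cells", "mito_gene_mask"]


@dataclass
class QCMetrics:
    f_mt: np.ndarray
    genes_detected: np.ndarray
    total_umi: np.ndarray


@dataclass
class QCReport:
    excluded: pd.DataFrame  # barcode/index -> reason in {high_fmt, count_outlier, both, kept}
    type_stats: pd.DataFrame  # per type: mean/sd of f_mt, tail cutoffs

    @property
    def kept_mask(self) -> np.ndarray:
        return (self.excluded["reason"] == "kept").to_numpy()


def mito_gene_mask(matrix: CountMatrix) -> np.ndarray:
    """Mitochondrial genes by chromosome tag 'MT' or an Mt- symbol prefix."""
    mask = np.zeros(matrix.n_genes, dtype=bool)
    if "chrom" in matrix.gene_meta.columns:
        mask |= (matrix.gene_meta["chrom"].to_numpy() == "MT")
    mask |= np.array(
        [s.lower().startswith(("mt-", "mt_")) for s in matrix.gene_symbols]
    )
    return mask


def qc_metrics(matrix: CountMatrix, mito_genes: np.ndarray | None = None) -> QCMetrics:
    """f_MT, genes detected, and total UMI per cell.

    ``mito_genes`` is a boolean mask or index array over genes; when omitted
    it is derived from the chromosome tag / symbol prefix.
    """
    if mito_genes is None:
        mito_genes = mito_gene_mask(matrix)
    mito_genes = np.asarray(mito_genes)
    if mito_genes.dtype != bool:
        m = np.zeros(matrix.n_genes, dtype=bool)
        m[mito_genes] = True
        mito_genes = m
    total = matrix.total_umi.astype(float)
    if not mito_genes.any():
        warnings.warn("no mitochondrial genes identified; f_MT set to 0")
        f_mt = np.zeros(matrix.n_cells)
    else:
        mito_total = np.asarray(matrix.counts[mito_genes].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore"):
            f_mt = np.where(total > 0, mito_total / np.maximum(total, 1), 0.0)
    genes_detected = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
    return QCMetrics(f_mt=f_mt, genes_detected=genes_detected, total_umi=matrix.total_umi)


def filter_cells(
    metrics: QCMetrics,
    labels: np.ndarray,
    fmt_sd_k: float = 2.0,
    tail: float = 0.015,
    min_cells: int = 10,
) -> QCReport:
    """Apply per-type f_MT and count-outlier exclusions.

    Within each type independently: cells with f_MT above mean + k*sd are
    excluded (upper tail only), and cells in the highest or lowest ``tail``
    fraction of the genes-per-cell or total-UMI distributions are excluded
    (tails per distribution, union of the two).  Quantile cutoffs use
    midpoint interpolation; cells exactly at a cutoff are kept.  Types with
    fewer than ``min_cells`` cells are skipped.
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n != len(metrics.f_mt):
        raise ValueError("labels do not match metrics")
    high_fmt = np.zeros(n, dtype=bool)
    outlier = np.zeros(n, dtype=bool)
    stats = []
    for t in pd.unique(labels):
        idx = np.flatnonzero(labels == t)
        if idx.size < min_cells:
            warnings.warn(f"type {t}: only {idx.size} cells; QC rules skipped")
            continue
        f = metrics.f_mt[idx]
        cutoff = f.mean() + fmt_sd_k * f.std(ddof=0)
        high_fmt[idx] = f > cutoff
        row = {"type": t, "fmt_mean": f.mean(), "fmt_sd": f.std(ddof=0), "fmt_cutoff": cutoff}
        if tail > 0:
            for name, values in (
                ("genes", metrics.genes_detected[idx].astype(float)),
                ("umi", metrics.total_umi[idx].astype(float)),
            ):
                lo = np.quantile(values, tail, method="midpoint")
                hi = np.quantile(values, 1.0 - tail, method="midpoint")
                outlier[idx] |= (values < lo) | (values > hi)
                row[f"{name}_lo"], row[f"{name}_hi"] = lo, hi
        stats.append(row)
    reason = np.where(
        high_fmt & outlier,
        "both",
        np.where(high_fmt, "high_fmt", np.where(outlier, "count_outlier", "kept")),
    )
    excluded = pd.DataFrame({"type": labels, "reason": reason})
    return QCReport(excluded=excluded, type_stats=pd.DataFrame(stats))
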