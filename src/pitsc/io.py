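"""Reading/writing 10x-layout count matrices, normalization, and symbol renaming.

A dataset is a directory per sample holding ``matrix.mtx`` (MatrixMarket
coordinate integer, genes as rows, 1-based indices), ``features.tsv``
(gene id, symbol and optionally chromosome) and ``barcodes.tsv``; an
optional ``samples.tsv`` sidecar maps barcodes to sex and replicate.
Gzip-compressed variants (``*.gz``) are accepted.

Normalization follows the convention of dividing each cell's UMI counts by
its total and rescaling by the median total UMI count per cell, so that
every cell's normalized column sums to the same library size.  Log
expression is ``log10(E + 1)``.
"""

from __future__ import annotations

import gzip
import io as _io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "FormatError",
    "read_tenx",
    "normalize",
    "rename_symbols",
]


class FormatError(ValueError):
    """Raised when an on-disk matrix does not conform to the 10x dialect."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with gene and cell metadata."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)  # sex, replicate, sample
    gene_meta: pd.DataFrame = field(default=None)  # chrom tag etc.

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise FormatError("gene metadata length does not match row count")
        if len(self.barcodes) != n_cells:
            raise FormatError("barcode count does not match column count")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        if self.gene_meta is None:
            self.gene_meta = pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id"))
        if (self.counts.data < 0).any():
            raise FormatError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def total_umi(self) -> np.ndarray:
        """Per-cell total UMI count."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[:, index],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            barcodes=self.barcodes[index],
            cell_meta=self.cell_meta.iloc[index],
            gene_meta=self.gene_meta,
        )

    def symbol_index(self, symbols: Iterable[str]) -> np.ndarray:
        """Row indices for gene symbols; missing symbols are skipped."""
        lookup = {}
        for i, s in enumerate(self.gene_symbols):
            lookup.setdefault(s, i)
        return np.array([lookup[s] for s in symbols if s in lookup], dtype=int)


@dataclass
class NormalizedMatrix:
    """Dense normalized expression E and its log10(E+1) transform."""

    E: np.ndarray
    log_expr: np.ndarray
    median_total: float

    @property
    def n_genes(self) -> int:
        return self.E.shape[0]

    @property
    def n_cells(self) -> int:
        return self.E.shape[1]

    def subset_cells(self, index: np.ndarray) -> "NormalizedMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return NormalizedMatrix(
            E=self.E[:, index], log_expr=self.log_expr[:, index], median_total=self.median_total
        )


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {directory}")


def _read_one(directory: Path) -> CountMatrix:
    directory = Path(directory)
    mtx_path = _find_file(directory, "matrix.mtx")
    feat_path = None
    for stem in ("features.tsv", "genes.tsv"):
        try:
            feat_path = _find_file(directory, stem)
            break
        except FormatError:
            continue
    if feat_path is None:
        raise FormatError(f"missing features.tsv in {directory}")
    bc_path = _find_file(directory, "barcodes.tsv")

    with _open_maybe_gzip(mtx_path) as fh:
        text = fh.read()
    _validate_triplets(text)
    counts = mmread(_io.StringIO(text))
    counts = sp.csr_matrix(counts)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].to_numpy()
    if counts.shape[0] != len(feats) or counts.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix dimensions {counts.shape} do not match features "
            f"({len(feats)}) / barcodes ({len(barcodes)})"
        )
    gene_ids = feats[0].to_numpy()
    gene_symbols = feats[1].to_numpy() if feats.shape[1] > 1 else gene_ids.copy()
    gene_meta = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if feats.shape[1] > 2:
        gene_meta["chrom"] = feats[2].to_numpy()

    cell_meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    samples_path = directory / "samples.tsv"
    if samples_path.exists():
        samp = pd.read_csv(samples_path, sep="\t", dtype=str).set_index("barcode")
        cell_meta = cell_meta.join(samp)

    if counts.data.size and not np.allclose(counts.data, np.round(counts.data)):
        raise FormatError("non-integer UMI counts")
    counts.data = counts.data.astype(np.int64)
    return CountMatrix(counts, gene_ids, gene_symbols, barcodes, cell_meta, gene_meta)


def _validate_triplets(text: str) -> None:
    """Reject 0-based coordinate entries, which MatrixMarket forbids."""
    lines = text.splitlines()
    body = [ln for ln in lines if ln and not ln.startswith("%")]
    if not body:
        raise FormatError("empty MatrixMarket file")
    for ln in body[1:]:
        parts = ln.split()
        if len(parts) >= 2 and (int(parts[0]) < 1 or int(parts[1]) < 1):
            raise FormatError(f"0-based index in triplet line: {ln!r}")


def read_tenx(directory: Path | str | Sequence[Path | str]) -> CountMatrix:
    """Read one or several 10x-layout sample directories.

    Multiple directories are merged by requiring an identical gene universe
    (same ids in the same order — the aggregated-matrix case); cells are
    concatenated and the sample of origin recorded in ``cell_meta``.
    """
    if isinstance(directory, (str, Path)):
        dirs = [Path(directory)]
    else:
        dirs = [Path(d) for d in directory]
    parts = [_read_one(d) for d in dirs]
    if len(parts) == 1:
        m = parts[0]
        if "sample" not in m.cell_meta.columns:
            m.cell_meta = m.cell_meta.assign(sample=dirs[0].name)
        return m
    first = parts[0]
    for p in parts[1:]:
        if not np.array_equal(first.gene_ids, p.gene_ids):
            raise FormatError("sample directories have differing gene universes")
    counts = sp.hstack([p.counts for p in parts], format="csr")
    barcodes = np.concatenate(
        [
            np.array([f"{d.name}:{b}" for b in p.barcodes], dtype=object)
            for d, p in zip(dirs, parts)
        ]
    )
    metas = []
    for d, p in zip(dirs, parts):
        meta = p.cell_meta.copy()
        meta.index = [f"{d.name}:{b}" for b in p.barcodes]
        meta["sample"] = d.name
        metas.append(meta)
    cell_meta = pd.concat(metas)
    cell_meta.index.name = "barcode"
    return CountMatrix(
        counts, first.gene_ids, first.gene_symbols, barcodes, cell_meta, first.gene_meta
    )


def normalize(matrix: CountMatrix, median_total: float | None = None) -> NormalizedMatrix:
    """Normalize UMI counts to a common per-cell total.

    ``E[i, j] = counts[i, j] / total[j] * median(total)``; the median may be
    supplied to carry a previously frozen value onto a cell subset.
    """
    totals = matrix.total_umi.astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            "cells with zero total UMI must be excluded before normalization: "
            + ", ".join(map(str, matrix.barcodes[zero[:5]]))
        )
    if median_total is None:
        median_total = float(np.median(totals))
    dense = np.asarray(matrix.counts.todense(), dtype=float)
    E = dense / totals[None, :] * median_total
    return NormalizedMatrix(E=E, log_expr=np.log10(E + 1.0), median_total=median_total)


def rename_symbols(
    matrix: CountMatrix,
    rgd_table: Mapping[str, tuple] | pd.DataFrame,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Replace reference symbols with registry symbols under two rules.

    Rule ``prefix``: a symbol beginning with ``LOC`` or ``RGD`` is replaced
    when the table offers a more informative symbol (one not itself carrying
    such a prefix), keyed by gene id.  Rule ``location``: when the table
    records a genomic location (chrom, strand, start, stop) exactly matching
    the gene's and a different symbol, the symbol is replaced.  Counts, ids
    and shape are never modified; a rename report is returned alongside.
    """
    if isinstance(rgd_table, pd.DataFrame):
        table = {
            str(r["gene_id"]): (
                str(r["symbol"]),
                (r.get("chrom"), r.get("strand"), r.get("start"), r.get("stop")),
            )
            for _, r in rgd_table.iterrows()
        }
    else:
        table = {k: (v[0], v[1] if len(v) > 1 else None) for k, v in rgd_table.items()}

    loc_cols = ("chrom", "strand", "start", "stop")
    have_loc = all(c in matrix.gene_meta.columns for c in loc_cols)
    new_symbols = matrix.gene_symbols.copy()
    rows = []
    for i, (gid, sym) in enumerate(zip(matrix.gene_ids, matrix.gene_symbols)):
        entry = table.get(str(gid))
        if entry is None:
            continue
        new_sym, loc = entry
        if new_sym is None or new_sym == sym:
            continue
        rule = None
        if (sym.startswith("LOC") or sym.startswith("RGD")) and not (
            new_sym.startswith("LOC") or new_sym.startswith("RGD")
        ):
            rule = "prefix"
        elif have_loc and loc is not None:
            mine = tuple(matrix.gene_meta.iloc[i][c] for c in loc_cols)
            if tuple(loc) == mine:
                rule = "location"
        if rule:
            new_symbols[i] = new_sym
            rows.append({"gene_id": gid, "old_symbol": sym, "new_symbol": new_sym, "rule": rule})
    report = pd.DataFrame(rows, columns=["gene_id", "old_symbol", "new_symbol", "rule"])
    dup = report["new_symbol"].isin(
        pd.Series(new_symbols).value_counts().loc[lambda s: s > 1].index
    )
    report["duplicate"] = dup.to_numpy() if len(report) else np.array([], dtype=bool)
    if report.get("duplicate", pd.Series(dtype=bool)).any():
        warnings.warn("renaming produced duplicate symbols; gene ids remain the unique key")
    out = replace(matrix, gene_symbols=new_symbols)
    return out, report


def write_tenx(matrix: CountMatrix, directory: Path | str, overwrite: bool = False) -> Path:
    """Write a CountMatrix as a 10x-layout directory (uncompressed)."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"refusing to write into non-empty {directory}")
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.counts)
    with open(directory / "matrix.mtx", "wb") as fh:
        mmwrite(fh, coo, field="integer")
    feats = pd.DataFrame({"gene_id": matrix.gene_ids, "symbol": matrix.gene_symbols})
    if "chrom" in matrix.gene_meta.columns:
        feats["chrom"] = matrix.gene_meta["chrom"].to_numpy()
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if len(matrix.cell_meta.columns):
        matrix.cell_meta.reset_index().to_csv(directory / "samples.tsv", sep="\t", index=False)
    return directory
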