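"""Two-track differential expression and dominant/specific gene calling.

Per gene, expression differences across cell types are tested with the
non-parametric Kruskal-Wallis omnibus plus all-pairs rank-sum contrasts
(Bonferroni-corrected within gene), and differences in the proportion of
cells expressing above the gene threshold with a Pearson chi-square of the
type x expressing table plus pairwise two-proportion Z contrasts.  Omnibus
and contrast p-values are BH-adjusted across genes.  A gene is upregulated
in a type when either track passes in full — adjusted omnibus p and every
relevant adjusted contrast p below alpha, with the mean (or proportion)
higher than in every other type.

Dominant genes are upregulated genes expressed in at least ``min_pct``% of
the type's cells with either a >= ``fold``-fold higher mean or a
>= ``delta_pct`` percentage-point higher expressing proportion than every
other compared type; specific markers are dominant genes expressed in
fewer than ``spec_pct``% of cells of every other type.  Group targets (PIT
= FSC plus the hormone-producing types; HPC = C, G, T, S, L) require the
conditions for every in-group vs out-group pair.  Sex dimorphism within a
type uses the rank-sum test between sexes with the same dominance rules,
treating the two sexes as the two types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix
from .threshold import ExpressionCalls
from .synthetic import HPC_TYPES

__all__ = [
    "DETestResult",
    "DominanceCall",
    "de_tests",
    "call_dominant_specific",
    "sex_de",
    "GROUPS",
]

GROUPS: dict[str, list[str]] = {
    "HPC": list(HPC_TYPES),
    "PIT": ["FSC", *HPC_TYPES],
}


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p-values per row (normal approximation
    with tie correction, no continuity correction)."""
    n1, n2 = a.shape[1], b.shape[1]
    n = n1 + n2
    X = np.concatenate([a, b], axis=1)
    ranks = stats.rankdata(X, axis=1)
    r1 = ranks[:, :n1].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    tie_term = np.empty(X.shape[0])
    for g in range(X.shape[0]):
        _, cnt = np.unique(X[g], return_counts=True)
        tie_term[g] = float((cnt.astype(float) ** 3 - cnt).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u - n1 * n2 / 2.0) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 0] = 1.0
    return np.clip(p, 0.0, 1.0)


def two_proportion_z_p(
    x1: np.ndarray, n1: int, x2: np.ndarray, n2: int
) -> np.ndarray:
    """Vectorized two-sided pooled two-proportion Z-test p-values."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p1 - p2) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 0] = 1.0  # pooled proportion 0 or 1 implies equal proportions
    return np.clip(p, 0.0, 1.0)


def _chi2_independence_p(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Per-gene Pearson chi-square of the type x (expressing/not) table.

    ``counts``: genes x types expressing-cell counts; ``totals``: cells per
    type.  Genes expressed in no cell or in all cells get p = 1.
    """
    n = totals.sum()
    row = counts.sum(axis=1)  # total expressing per gene
    p_expr = row / n
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = p_expr[:, None] * totals[None, :]
        e0 = (1 - p_expr)[:, None] * totals[None, :]
        stat = ((counts - e1) ** 2 / e1 + ((totals[None, :] - counts) - e0) ** 2 / e0).sum(
            axis=1
        )
    df = len(totals) - 1
    p = stats.chi2.sf(stat, df)
    p[(row == 0) | (row == n)] = 1.0
    return p


@dataclass
class DETestResult:
    types: list[str]
    kw_p: np.ndarray
    kw_adj: np.ndarray
    chi2_p: np.ndarray
    chi2_adj: np.ndarray
    pair_expr_adj: dict[tuple[str, str], np.ndarray]
    pair_prop_adj: dict[tuple[str, str], np.ndarray]
    mean_expr: pd.DataFrame  # genes x types, on normalized expression E
    pct_expr: pd.DataFrame  # genes x types, percent expressing
    alpha: float = 0.001

    def _pair(self, t: str, u: str) -> tuple[str, str]:
        return (t, u) if (t, u) in self.pair_expr_adj else (u, t)

    def pair_pass(self, t: str, u: str) -> np.ndarray:
        """Genes where either track passes for the ordered contrast t > u."""
        key = self._pair(t, u)
        expr = (
            (self.kw_adj < self.alpha)
            & (self.pair_expr_adj[key] < self.alpha)
            & (self.mean_expr[t].to_numpy() > self.mean_expr[u].to_numpy())
        )
        prop = (
            (self.chi2_adj < self.alpha)
            & (self.pair_prop_adj[key] < self.alpha)
            & (self.pct_expr[t].to_numpy() > self.pct_expr[u].to_numpy())
        )
        return expr | prop

    def upregulated(self, t: str) -> np.ndarray:
        """Either track passes in full against every other type."""
        others = [u for u in self.types if u != t]
        expr = self.kw_adj < self.alpha
        prop = self.chi2_adj < self.alpha
        for u in others:
            key = self._pair(t, u)
            expr &= (self.pair_expr_adj[key] < self.alpha) & (
                self.mean_expr[t].to_numpy() > self.mean_expr[u].to_numpy()
            )
            prop &= (self.pair_prop_adj[key] < self.alpha) & (
                self.pct_expr[t].to_numpy() > self.pct_expr[u].to_numpy()
            )
        return expr | prop


def de_tests(
    norm: NormalizedMatrix,
    calls: ExpressionCalls,
    labels: np.ndarray,
    alpha: float = 0.001,
) -> DETestResult:
    """Run both DE tracks for every gene across the labeled cell types."""
    labels = np.asarray(labels, dtype=object)
    types = [t for t in pd.unique(labels)]
    if len(types) < 2:
        raise ValueError("need at least 2 types")
    masks = {t: labels == t for t in types}
    for t in types:
        if masks[t].sum() < 2:
            raise ValueError(f"type {t} has fewer than 2 cells")
    L = norm.log_expr
    n_genes = L.shape[0]

    groups = {t: L[:, masks[t]] for t in types}
    kw_p = np.ones(n_genes)
    for g in range(n_genes):
        samples = [groups[t][g] for t in types]
        flat = np.concatenate(samples)
        if np.all(flat == flat[0]):
            continue
        kw_p[g] = stats.kruskal(*samples).pvalue

    expr_counts = np.stack(
        [calls.calls[:, masks[t]].sum(axis=1) for t in types], axis=1
    ).astype(float)
    totals = np.array([masks[t].sum() for t in types], dtype=float)
    chi2_p = _chi2_independence_p(expr_counts, totals)

    n_pairs = len(types) * (len(types) - 1) // 2
    pair_expr_adj: dict[tuple[str, str], np.ndarray] = {}
    pair_prop_adj: dict[tuple[str, str], np.ndarray] = {}
    for (ti, t), (ui, u) in combinations(enumerate(types), 2):
        pe = rank_sum_p(groups[t], groups[u])
        pp = two_proportion_z_p(
            expr_counts[:, ti], int(totals[ti]), expr_counts[:, ui], int(totals[ui])
        )
        # Bonferroni within gene over the contrasts, then BH across genes
        pair_expr_adj[(t, u)] = multipletests(
            np.minimum(pe * n_pairs, 1.0), method="fdr_bh"
        )[1]
        pair_prop_adj[(t, u)] = multipletests(
            np.minimum(pp * n_pairs, 1.0), method="fdr_bh"
        )[1]

    mean_expr = pd.DataFrame({t: norm.E[:, masks[t]].mean(axis=1) for t in types})
    pct_expr = pd.DataFrame(
        {t: 100.0 * calls.calls[:, masks[t]].mean(axis=1) for t in types}
    )
    return DETestResult(
        types=types,
        kw_p=kw_p,
        kw_adj=multipletests(kw_p, method="fdr_bh")[1],
        chi2_p=chi2_p,
        chi2_adj=multipletests(chi2_p, method="fdr_bh")[1],
        pair_expr_adj=pair_expr_adj,
        pair_prop_adj=pair_prop_adj,
        mean_expr=mean_expr,
        pct_expr=pct_expr,
        alpha=alpha,
    )


@dataclass
class DominanceCall:
    calls: dict = field(default_factory=dict)  # target -> DataFrame
    params: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        parts = []
        for target, df in self.calls.items():
            part = df.copy()
            part.insert(0, "target", str(target))
            parts.append(part)
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


def _dominance_conditions(
    de: DETestResult,
    in_types: Sequence[str],
    out_types: Sequence[str],
    min_pct: float,
    fold: float,
    delta_pct: float,
    spec_pct: float,
) -> pd.DataFrame:
    n_genes = len(de.kw_p)
    upreg = np.ones(n_genes, dtype=bool)
    gate = np.ones(n_genes, dtype=bool)
    min_fold = np.full(n_genes, np.inf)
    min_delta = np.full(n_genes, np.inf)
    positives = de.mean_expr.to_numpy()
    floor = positives[positives > 0].min() if (positives > 0).any() else 1.0
    if len(in_types) == 1:
        upreg = de.upregulated(in_types[0])
    else:
        for t in in_types:
            for u in out_types:
                upreg &= de.pair_pass(t, u)
    for t in in_types:
        gate &= de.pct_expr[t].to_numpy() >= min_pct
        for u in out_types:
            mt = de.mean_expr[t].to_numpy()
            mu = de.mean_expr[u].to_numpy()
            pt = de.pct_expr[t].to_numpy()
            pu = de.pct_expr[u].to_numpy()
            cond_fold = (mu == 0) | (mt >= fold * mu)
            cond_delta = pt >= pu + delta_pct
            gate &= cond_fold | cond_delta
            min_fold = np.minimum(min_fold, mt / np.maximum(mu, floor))
            min_delta = np.minimum(min_delta, pt - pu)
    dominant = upreg & gate
    spec = dominant.copy()
    for u in out_types:
        spec &= de.pct_expr[u].to_numpy() < spec_pct
    return pd.DataFrame(
        {
            "upregulated": upreg,
            "dominant": dominant,
            "specific": spec,
            "min_fold": min_fold,
            "min_delta_pct": min_delta,
        }
    )


def call_dominant_specific(
    de: DETestResult,
    targets: Sequence[str] | None = None,
    min_pct: float = 20.0,
    fold: float = 3.0,
    delta_pct: float = 30.0,
    spec_pct: float = 5.0,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> DominanceCall:
    """Call dominant and specific genes for cell types and type groups."""
    groups = dict(GROUPS if groups is None else groups)
    if targets is None:
        targets = list(de.types) + [g for g in groups if set(groups[g]) <= set(de.types)]
    out = DominanceCall(
        params=dict(min_pct=min_pct, fold=fold, delta_pct=delta_pct, spec_pct=spec_pct)
    )
    for target in targets:
        if target in de.types:
            in_types = [target]
            out_types = [u for u in de.types if u != target]
        elif target in groups:
            in_types = [t for t in groups[target]]
            missing = [t for t in in_types if t not in de.types]
            if missing:
                raise ValueError(f"group {target}: types {missing} absent from DE result")
            out_types = [u for u in de.types if u not in in_types]
        else:
            raise ValueError(f"unknown target {target!r}")
        if not out_types:
            raise ValueError(f"target {target!r} leaves no comparison types")
        out.calls[target] = _dominance_conditions(
            de, in_types, out_types, min_pct, fold, delta_pct, spec_pct
        )
    return out


def sex_de(
    norm: NormalizedMatrix,
    calls: ExpressionCalls,
    labels: np.ndarray,
    sex: np.ndarray,
    alpha: float = 0.001,
    min_pct: float = 20.0,
    fold: float = 3.0,
    delta_pct: float = 30.0,
    spec_pct: float = 5.0,
    sexes: tuple[str, str] = ("F", "M"),
) -> DominanceCall:
    """Within-type sex dimorphism: rank-sum and proportion tracks, BH across
    genes, then the standard dominance rules with the sexes as the types."""
    labels = np.asarray(labels, dtype=object)
    sex = np.asarray(sex, dtype=object)
    out = DominanceCall(
        params=dict(alpha=alpha, min_pct=min_pct, fold=fold, delta_pct=delta_pct,
                    spec_pct=spec_pct)
    )
    for t in pd.unique(labels):
        in_type = labels == t
        m = {s: in_type & (sex == s) for s in sexes}
        if any(m[s].sum() < 2 for s in sexes):
            warnings.warn(f"type {t}: a sex is absent or has < 2 cells; skipped")
            continue
        a, b = (norm.log_expr[:, m[s]] for s in sexes)
        rs_adj = multipletests(rank_sum_p(a, b), method="fdr_bh")[1]
        x = {s: calls.calls[:, m[s]].sum(axis=1).astype(float) for s in sexes}
        n = {s: int(m[s].sum()) for s in sexes}
        z_adj = multipletests(
            two_proportion_z_p(x[sexes[0]], n[sexes[0]], x[sexes[1]], n[sexes[1]]),
            method="fdr_bh",
        )[1]
        mean = {s: norm.E[:, m[s]].mean(axis=1) for s in sexes}
        pct = {s: 100.0 * x[s] / n[s] for s in sexes}
        for w, o in (sexes, sexes[::-1]):
            upreg = ((rs_adj < alpha) & (mean[w] > mean[o])) | (
                (z_adj < alpha) & (pct[w] > pct[o])
            )
            gate = (pct[w] >= min_pct) & (
                ((mean[o] == 0) | (mean[w] >= fold * mean[o]))
                | (pct[w] >= pct[o] + delta_pct)
            )
            dominant = upreg & gate
            specific = dominant & (pct[o] < spec_pct)
            floor = mean[o][mean[o] > 0].min() if (mean[o] > 0).any() else 1.0
            out.calls[(t, w)] = pd.DataFrame(
                {
                    "upregulated": upreg,
                    "dominant": dominant,
                    "specific": specific,
                    "min_fold": mean[w] / np.maximum(mean[o], floor),
                    "min_delta_pct": pct[w] - pct[o],
                }
            )
    return out
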