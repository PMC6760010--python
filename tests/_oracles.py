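"""Independent brute-force oracles used to cross-check the implementations."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    """Argmax of between-class variance over all candidate bin edges,
    computed from scratch with direct masked class statistics."""
    v = np.asarray(values, dtype=float)
    edges = np.linspace(v.min(), v.max(), n_bins + 1)
    n = v.size
    best, best_t = -1.0, float(edges[0])
    for t in edges[:n_bins]:
        upper = v >= t
        w1 = int(upper.sum())
        if w1 == 0 or w1 == n:
            sb2 = 0.0
        else:
            w0 = n - w1
            sb2 = (w0 / n) * (w1 / n) * (v[~upper].mean() - v[upper].mean()) ** 2
        if sb2 > best:
            best, best_t = sb2, float(t)
    return best_t


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values: p_(i) / (i/m), monotonized from
    the largest rank down and clipped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] / (np.arange(1, m + 1) / m)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.where(adj > 1.0, 1.0, adj)
    out = np.empty(m)
    out[order] = adj
    return out


def hypergeom_upper_tail(s: int, population: int, successes: int, draws: int) -> Fraction:
    """P(X >= s) for X ~ Hypergeometric, by exact enumeration."""
    total = Fraction(0)
    denom = comb(population, draws)
    for x in range(max(s, 0), min(successes, draws) + 1):
        if draws - x <= population - successes:
            total += Fraction(comb(successes, x) * comb(population - successes, draws - x), denom)
    return total


def nearest_gap_scan(genes: list, target) -> int | None:
    """Intervening bases from the target gene's 3' boundary to the nearest
    other gene boundary in the 3' direction, by exhaustive scan."""
    best = None
    for g in genes:
        if g is target or g.chrom != target.chrom:
            continue
        for b in (g.start, g.end):
            if target.strand == "+" and b > target.end:
                gap = b - target.end - 1
            elif target.strand == "-" and b < target.start:
                gap = target.start - b - 1
            else:
                continue
            best = gap if best is None else min(best, gap)
    return best
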