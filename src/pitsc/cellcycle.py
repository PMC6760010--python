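"""Iterative mitotic marker refinement and proliferating-cell calling.

A cell-cycle score counts, per cell, how many genes of the current marker
list are expressed above their Otsu thresholds.  An Otsu threshold on the
integer score distribution (one bin per observed score) splits candidate
proliferating cells (score strictly above the threshold) from the rest.
The marker list is then rebuilt: genes significantly upregulated in the
candidates (rank-sum, BH-adjusted p < alpha), expressed above threshold in
at least half of the candidates and under 5% of the remaining cells, and
annotated to the mitotic cell cycle (GO:0000278).  Scoring and selection
alternate until both the marker list and the candidate set are fixed.

The packaged seed list is a small curated set of canonical mitotic genes;
any user list is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from statsmodels.stats.multitest import multipletests

from .diffexp import rank_sum_p
from .io import NormalizedMatrix
from .threshold import ExpressionCalls, otsu_threshold_discrete

__all__ = ["CycleState", "iterate_cycle_markers", "load_gene_list", "packaged_gene_list"]


@dataclass
class CycleState:
    markers: list[str]
    score: np.ndarray  # per cell integer
    score_threshold: float
    candidates: np.ndarray  # per cell bool, score > threshold
    iteration: int
    converged: bool
    history: list[dict] = field(default_factory=list)


def packaged_gene_list(name: str) -> list[str]:
    """Load a packaged gene list ('cycle_seed_genes' or 'go_mitotic_genes')."""
    text = resources.files("pitsc.data").joinpath(f"{name}.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def _score(calls: ExpressionCalls, gene_symbols: np.ndarray, markers: list[str]) -> np.ndarray:
    lookup: dict[str, int] = {}
    for i, s in enumerate(gene_symbols):
        lookup.setdefault(s, i)
    rows = [lookup[g] for g in markers if g in lookup]
    if not rows:
        return np.zeros(calls.calls.shape[1], dtype=int)
    return calls.calls[rows].sum(axis=0).astype(int)


def iterate_cycle_markers(
    calls: ExpressionCalls,
    norm: NormalizedMatrix,
    gene_symbols: np.ndarray,
    seed_list: list[str],
    go_mitotic: list[str] | set[str],
    alpha: float = 0.001,
    max_iter: int = 20,
    min_in_pct: float = 50.0,
    max_out_pct: float = 5.0,
) -> CycleState:
    """Refine the cycle marker list and candidate set to a fixed point."""
    if not seed_list:
        raise ValueError("empty seed list")
    go = set(go_mitotic)
    markers = sorted(set(seed_list))
    candidates = np.zeros(calls.calls.shape[1], dtype=bool)
    state = None
    for iteration in range(1, max_iter + 1):
        score = _score(calls, gene_symbols, markers)
        thr = otsu_threshold_discrete(score)
        if np.isnan(thr):
            warnings.warn("degenerate score distribution; no proliferating cells")
            return CycleState(markers, score, np.nan, np.zeros_like(candidates), iteration, True)
        new_candidates = score > thr
        if not new_candidates.any():
            warnings.warn("empty candidate set; no proliferating cells")
            return CycleState(markers, score, thr, new_candidates, iteration, True)

        inside = norm.log_expr[:, new_candidates]
        outside = norm.log_expr[:, ~new_candidates]
        adj = multipletests(rank_sum_p(inside, outside), method="fdr_bh")[1]
        up = (adj < alpha) & (inside.mean(axis=1) > outside.mean(axis=1))
        pct_in = 100.0 * calls.calls[:, new_candidates].mean(axis=1)
        pct_out = 100.0 * calls.calls[:, ~new_candidates].mean(axis=1)
        keep = up & (pct_in >= min_in_pct) & (pct_out < max_out_pct)
        new_markers = sorted(
            {s for s in gene_symbols[keep] if s in go}
        )
        state = CycleState(
            markers=new_markers,
            score=score,
            score_threshold=thr,
            candidates=new_candidates,
            iteration=iteration,
            converged=False,
        )
        state.history.append(
            {"iteration": iteration, "n_markers": len(new_markers),
             "n_candidates": int(new_candidates.sum()), "threshold": thr}
        )
        if new_markers == markers and np.array_equal(new_candidates, candidates):
            state.converged = True
            return state
        markers, candidates = new_markers, new_candidates
        if not markers:
            warnings.warn("marker list emptied; no proliferating cells")
            state.candidates = np.zeros_like(new_candidates)
            state.converged = True
            return state
    warnings.warn(f"no fixed point within {max_iter} iterations")
    return state
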