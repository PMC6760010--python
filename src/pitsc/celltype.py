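"""Hierarchical marker-rule cell classification and kNN label imputation.

Cells are typed by "expression above threshold in at least k of a marker
set" rules in two tiers: first the major classes — erythrocytes (E),
leukocytes (Le), endothelial cells (EC), folliculostellate cells (FSC) and
hormone-producing cells (HPC) — then, within HPC, the subtypes C, G, T, S,
L.  Exclusion rules (pericytes, melanotrophs, posterior-lobe tissue) take
precedence over typing.  A cell satisfying more than one rule at a tier is
ambiguous; one satisfying none is unclassified and may later be rescued by
majority vote over its nearest same-sex neighbors in PC space.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .synthetic import CONTAMINANT_MARKERS, DEFAULT_MARKERS
from .threshold import ExpressionCalls

__all__ = [
    "MarkerRule",
    "RuleSet",
    "Classification",
    "default_ruleset",
    "classify_cells",
    "impute_labels",
    "AMBIGUOUS",
    "UNCLASSIFIED",
]

AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"


@dataclass
class MarkerRule:
    label: str
    genes: list[str]
    min_hits: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_hits <= len(self.genes)):
            raise ValueError(f"rule {self.label}: min_hits outside [1, |genes|]")


@dataclass
class RuleSet:
    exclusion_rules: list[MarkerRule] = field(default_factory=list)
    tier1: list[MarkerRule] = field(default_factory=list)
    tier2: list[MarkerRule] = field(default_factory=list)
    tier2_parent: str = "HPC"

    def __post_init__(self) -> None:
        labels = [r.label for r in self.exclusion_rules + self.tier1 + self.tier2]
        if len(labels) != len(set(labels)):
            raise ValueError("rule labels must be unique")


def default_ruleset() -> RuleSet:
    """The anterior-pituitary rules: 3 exclusion classes, 5 major, 5 HPC subtypes."""
    excl = [MarkerRule(t, list(g), 2) for t, g in CONTAMINANT_MARKERS.items()]
    tier1 = [
        MarkerRule(t, list(DEFAULT_MARKERS[t]), 2) for t in ("E", "Le", "EC", "FSC", "HPC")
    ]
    tier2 = [
        MarkerRule("C", list(DEFAULT_MARKERS["C"]), 2),
        MarkerRule("G", list(DEFAULT_MARKERS["G"]), 2),
        MarkerRule("T", list(DEFAULT_MARKERS["T"]), 2),
        MarkerRule("S", list(DEFAULT_MARKERS["S"]), 1),
        MarkerRule("L", list(DEFAULT_MARKERS["L"]), 1),
    ]
    return RuleSet(exclusion_rules=excl, tier1=tier1, tier2=tier2)


@dataclass
class Classification:
    label: np.ndarray  # per cell
    provenance: np.ndarray  # per cell in {rule, imputed}

    def counts(self) -> Counter:
        return Counter(self.label.tolist())


def _rule_hits(calls: ExpressionCalls, gene_symbols: np.ndarray, rule: MarkerRule) -> np.ndarray:
    lookup: dict[str, int] = {}
    for i, s in enumerate(gene_symbols):
        lookup.setdefault(s, i)
    rows = [lookup[g] for g in rule.genes if g in lookup]
    missing = [g for g in rule.genes if g not in lookup]
    if missing:
        warnings.warn(f"rule {rule.label}: markers {missing} absent; dropped")
    k = min(rule.min_hits, len(rows))
    if not rows:
        return np.zeros(calls.calls.shape[1], dtype=bool)
    hits = calls.calls[rows].sum(axis=0)
    return hits >= k


def classify_cells(
    calls: ExpressionCalls, gene_symbols: np.ndarray, rules: RuleSet
) -> Classification:
    """Apply exclusion then tiered marker rules to every cell."""
    if not rules.tier1:
        raise ValueError("empty rule set")
    n_cells = calls.calls.shape[1]
    label = np.array([UNCLASSIFIED] * n_cells, dtype=object)

    excluded = np.zeros(n_cells, dtype=bool)
    for rule in rules.exclusion_rules:
        sat = _rule_hits(calls, gene_symbols, rule) & ~excluded
        label[sat] = f"excluded:{rule.label}"
        excluded |= sat

    tier1_sat = np.stack(
        [_rule_hits(calls, gene_symbols, r) for r in rules.tier1], axis=0
    )
    tier1_sat[:, excluded] = False
    n_sat = tier1_sat.sum(axis=0)
    free = ~excluded
    label[free & (n_sat > 1)] = AMBIGUOUS
    for r_i, rule in enumerate(rules.tier1):
        only = free & (n_sat == 1) & tier1_sat[r_i]
        label[only] = rule.label

    if rules.tier2:
        parent = label == rules.tier2_parent
        tier2_sat = np.stack(
            [_rule_hits(calls, gene_symbols, r) for r in rules.tier2], axis=0
        )
        tier2_sat[:, ~parent] = False
        n2 = tier2_sat.sum(axis=0)
        label[parent & (n2 > 1)] = AMBIGUOUS
        label[parent & (n2 == 0)] = UNCLASSIFIED
        for r_i, rule in enumerate(rules.tier2):
            label[parent & (n2 == 1) & tier2_sat[r_i]] = rule.label

    provenance = np.array(["rule"] * n_cells, dtype=object)
    return Classification(label=label, provenance=provenance)


def impute_labels(
    pc_scores: np.ndarray,
    cls: Classification,
    sex: np.ndarray,
    k: int = 30,
) -> Classification:
    """Assign unclassified cells the majority label of their k nearest
    same-sex neighbors in PC space (Euclidean).

    A cell stays unclassified when the winning neighbor label is ambiguous,
    unclassified, or an exclusion class, or when the vote ties.  Ambiguous
    cells are never imputed, and no rule-derived label is ever changed.
    """
    sex = np.asarray(sex, dtype=object)
    label = cls.label.copy()
    provenance = cls.provenance.copy()
    unc = np.flatnonzero(label == UNCLASSIFIED)
    for s in np.unique(sex):
        pool = np.flatnonzero(sex == s)
        if pool.size <= k:
            raise ValueError(f"fewer than k+1 cells of sex {s}")
        targets = [i for i in unc if sex[i] == s]
        if not targets:
            continue
        nn = NearestNeighbors(n_neighbors=k + 1).fit(pc_scores[pool])
        _, nbr = nn.kneighbors(pc_scores[targets])
        for row, i in zip(nbr, targets):
            neighbors = [pool[j] for j in row if pool[j] != i][:k]
            votes = Counter(cls.label[neighbors].tolist())
            (top, top_n), *rest = votes.most_common()
            if rest and rest[0][1] == top_n:
                continue  # tie -> stays unclassified
            if top in (AMBIGUOUS, UNCLASSIFIED) or top.startswith("excluded:"):
                continue
            label[i] = top
            provenance[i] = "imputed"
    return Classification(label=label, provenance=provenance)
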