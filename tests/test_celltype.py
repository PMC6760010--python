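import numpy as np
import pytest

from pitsc.celltype import (
    AMBIGUOUS,
    UNCLASSIFIED,
    Classification,
    MarkerRule,
    RuleSet,
    classify_cells,
    default_ruleset,
    impute_labels,
)
from pitsc.threshold import ExpressionCalls, GeneThresholds


def calls_from_symbols(on_sets, symbols):
    """Build an ExpressionCalls where cell j expresses exactly on_sets[j]."""
    calls = np.zeros((len(symbols), len(on_sets)), dtype=bool)
    lookup = {s: i for i, s in enumerate(symbols)}
    for j, on in enumerate(on_sets):
        for g in on:
            calls[lookup[g], j] = True
    thr = GeneThresholds(np.zeros(len(symbols)), np.zeros(len(symbols), dtype=bool))
    return ExpressionCalls(calls=calls, thresholds=thr)


SYMBOLS = [
    "Hbb", "Hba-a1", "Resp18", "Uchl1", "Chgb", "Scg2", "Gh1", "Pomc", "Pcsk2",
    "Pax7", "Crhr1", "S100b", "Fxyd1", "Cga", "Lhb", "Tshb", "Trhr", "Prl",
    "Gfap", "Avp", "Oxt", "Lhx2",
]


def test_marker_rules_classify_canonical_cells():
    cells = [
        {"Hbb", "Hba-a1"},                            # erythrocyte: 2 hemoglobins
        {"Resp18", "Uchl1", "Gh1"},                   # HPC with Gh1 only -> S (1 marker suffices)
        {"Resp18", "Uchl1", "Prl"},                   # HPC with Prl -> L
        {"Resp18", "Chgb", "Pomc", "Crhr1"},          # HPC with 2 of C set -> C
        {"S100b", "Fxyd1", "Resp18", "Scg2"},         # satisfies FSC and HPC -> ambiguous
        {"Resp18", "Uchl1"},                          # HPC, no subtype hit -> unclassified
        set(),                                        # nothing -> unclassified
        {"Pomc", "Pcsk2"},                            # melanotroph exclusion
        {"Resp18", "Uchl1", "Cga", "Lhb", "Tshb"},    # G and T both satisfied -> ambiguous
    ]
    cls = classify_cells(calls_from_symbols(cells, SYMBOLS), np.array(SYMBOLS), default_ruleset())
    assert list(cls.label) == [
        "E", "S", "L", "C", AMBIGUOUS, UNCLASSIFIED, UNCLASSIFIED,
        "excluded:melanotroph", AMBIGUOUS,
    ]


def test_exclusion_takes_precedence_over_typing():
    # satisfies melanotroph (Pomc+Pcsk2) and the full C criterion: excluded, never ambiguous
    cells = [{"Pomc", "Pcsk2", "Crhr1", "Resp18", "Uchl1"}]
    cls = classify_cells(calls_from_symbols(cells, SYMBOLS), np.array(SYMBOLS), default_ruleset())
    assert cls.label[0] == "excluded:melanotroph"


def test_rule_validation():
    with pytest.raises(ValueError):
        MarkerRule("X", ["a", "b"], 3)
    with pytest.raises(ValueError):
        RuleSet(tier1=[MarkerRule("X", ["a"], 1), MarkerRule("X", ["b"], 1)])
    with pytest.raises(ValueError):
        classify_cells(
            calls_from_symbols([set()], SYMBOLS), np.array(SYMBOLS), RuleSet(tier1=[])
        )


def test_classification_is_permutation_equivariant(nine_type, nine_type_calls):
    _, matrix, _ = nine_type
    rules = default_ruleset()
    cls = classify_cells(nine_type_calls, matrix.gene_symbols, rules)
    rng = np.random.default_rng(7)
    perm = rng.permutation(matrix.n_cells)
    shuffled = ExpressionCalls(
        calls=nine_type_calls.calls[:, perm], thresholds=nine_type_calls.thresholds
    )
    cls_perm = classify_cells(shuffled, matrix.gene_symbols, rules)
    assert np.array_equal(cls_perm.label, cls.label[perm])


def test_rule_accuracy_on_planted_types(nine_type, nine_type_calls):
    _, matrix, truth = nine_type
    cls = classify_cells(nine_type_calls, matrix.gene_symbols, default_ruleset())
    assert (cls.label == truth.cell_type).mean() >= 0.95


def _embedding_classification(labels):
    return Classification(
        label=np.array(labels, dtype=object),
        provenance=np.array(["rule"] * len(labels), dtype=object),
    )


def test_imputation_rescues_a_cell_inside_a_pure_cluster(rng):
    pcs = np.concatenate([rng.normal(0, 0.1, (40, 3)), [[0.0, 0.0, 0.0]]])
    cls = _embedding_classification(["S"] * 40 + [UNCLASSIFIED])
    sex = np.array(["F"] * 41)
    out = impute_labels(pcs, cls, sex, k=30)
    assert out.label[-1] == "S"
    assert out.provenance[-1] == "imputed"
    assert np.array_equal(out.label[:40], cls.label[:40])  # no rule label flips


def test_majority_unclassified_neighbors_block_imputation(rng):
    pcs = rng.normal(0, 0.1, (31, 3))
    cls = _embedding_classification([UNCLASSIFIED] * 16 + ["S"] * 14 + [UNCLASSIFIED])
    out = impute_labels(pcs, cls, np.array(["F"] * 31), k=30)
    assert out.label[-1] == UNCLASSIFIED


def test_single_neighbor_vote(rng):
    pcs = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]])
    cls = _embedding_classification(["G", UNCLASSIFIED, "S"])
    out = impute_labels(pcs, cls, np.array(["M"] * 3), k=1)
    assert out.label[1] == "G"


def test_tied_vote_stays_unclassified(rng):
    pcs = np.concatenate([rng.normal(0, 0.05, (15, 2)), rng.normal(0.02, 0.05, (15, 2)),
                          [[0.0, 0.0]]])
    cls = _embedding_classification(["G"] * 15 + ["S"] * 15 + [UNCLASSIFIED])
    out = impute_labels(pcs, cls, np.array(["F"] * 31), k=30)
    assert out.label[-1] == UNCLASSIFIED


def test_imputation_only_touches_unclassified(rng):
    pcs = rng.normal(0, 1, (60, 4))
    labels = ["S"] * 30 + ["G"] * 20 + [AMBIGUOUS] * 5 + [UNCLASSIFIED] * 5
    cls = _embedding_classification(labels)
    out = impute_labels(pcs, cls, np.array(["F"] * 60), k=10)
    changed = out.label != cls.label
    assert set(np.array(labels, dtype=object)[changed]) <= {UNCLASSIFIED}
    assert (out.provenance[changed] == "imputed").all()
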