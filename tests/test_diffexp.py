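import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from statsmodels.stats.proportion import proportions_ztest

import pitsc
from pitsc import threshold
from pitsc.diffexp import (
    DETestResult,
    call_dominant_specific,
    de_tests,
    rank_sum_p,
    sex_de,
    two_proportion_z_p,
)


@pytest.fixture(scope="module")
def four_type():
    config = pitsc.pituitary_config(
        n_cells_per_type={t: {"F": 100, "M": 100} for t in ("E", "Le", "EC", "FSC")},
        doublet_rate=0.0,
        cycling_fraction=0.0,
        seed=4,
    )
    matrix, truth = pitsc.generate_dataset(config)
    norm = pitsc.normalize(matrix)
    calls = threshold.expression_calls(norm)
    de = de_tests(norm, calls, truth.cell_type)
    return matrix, truth, norm, calls, de


def test_rank_sum_matches_mann_whitney(rng):
    a = rng.poisson(2.0, (30, 40)).astype(float)
    b = rng.poisson(2.5, (30, 55)).astype(float)
    mine = rank_sum_p(a, b)
    ref = np.array(
        [
            mannwhitneyu(
                a[g], b[g], alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            for g in range(30)
        ]
    )
    np.testing.assert_allclose(mine, ref, rtol=1e-12)
    # identical samples: p = 1
    same = np.ones((3, 10))
    np.testing.assert_array_equal(rank_sum_p(same, same), 1.0)


def test_two_proportion_z_matches_statsmodels(rng):
    x1 = rng.integers(0, 100, 40).astype(float)
    x2 = rng.integers(0, 100, 40).astype(float)
    mine = two_proportion_z_p(x1, 100, x2, 100)
    ref = np.array([proportions_ztest([x1[i], x2[i]], [100, 100])[1] for i in range(40)])
    np.testing.assert_allclose(mine, ref, rtol=1e-12)
    # 0.9 vs 0.1 with n = 200 each is overwhelming evidence
    assert two_proportion_z_p(np.array([180.0]), 200, np.array([20.0]), 200)[0] < 1e-10
    # degenerate pooled proportions
    assert two_proportion_z_p(np.array([0.0]), 50, np.array([0.0]), 60)[0] == 1.0
    assert two_proportion_z_p(np.array([50.0]), 50, np.array([60.0]), 60)[0] == 1.0


def test_planted_markers_are_called_in_their_type(four_type):
    matrix, truth, norm, calls, de = four_type
    dom = call_dominant_specific(de, targets=list(de.types))
    symbols = list(matrix.gene_symbols)
    for t, markers in [("E", ["Hbb", "Hba-a1"]), ("Le", ["Cd53", "Tyrobp"]),
                       ("FSC", ["S100b", "Gstm2"])]:
        for g in markers:
            i = symbols.index(g)
            frame = dom.calls[t]
            assert frame["upregulated"][i], (t, g)
            assert frame["dominant"][i], (t, g)
            assert frame["specific"][i], (t, g)


def test_null_genes_are_not_called(four_type):
    matrix, truth, norm, calls, de = four_type
    dom = call_dominant_specific(de, targets=list(de.types))
    null = np.array([s.startswith("Gene") for s in matrix.gene_symbols])
    upreg_any = np.zeros(matrix.n_genes, dtype=bool)
    for t in de.types:
        upreg_any |= dom.calls[t]["upregulated"].to_numpy()
    assert upreg_any[null].mean() <= 0.005


def test_inclusion_chain_holds_everywhere(four_type):
    *_, de = four_type
    dom = call_dominant_specific(de, targets=list(de.types))
    for frame in dom.calls.values():
        assert not (frame["specific"] & ~frame["dominant"]).any()
        assert not (frame["dominant"] & ~frame["upregulated"]).any()


def test_a_specific_gene_is_dominant_nowhere_else(four_type):
    *_, de = four_type
    dom = call_dominant_specific(de, targets=list(de.types))
    types = list(de.types)
    for t in types:
        spec = dom.calls[t]["specific"].to_numpy()
        for u in types:
            if u == t:
                continue
            assert not (spec & dom.calls[u]["dominant"].to_numpy()).any()


def _craft_de(mean, pct, sig=True):
    """DETestResult with every test passing (or failing) uniformly."""
    types = list(mean.columns)
    n = len(mean)
    p = np.full(n, 1e-9 if sig else 1.0)
    pairs = {}
    from itertools import combinations

    for t, u in combinations(types, 2):
        pairs[(t, u)] = p.copy()
    return DETestResult(
        types=types, kw_p=p, kw_adj=p, chi2_p=p, chi2_adj=p,
        pair_expr_adj=pairs, pair_prop_adj={k: v.copy() for k, v in pairs.items()},
        mean_expr=mean, pct_expr=pct,
    )


def test_dominance_thresholds_are_enforced():
    # gene 0: fold 2.1 and delta 20 -> fails both dominance conditions
    # gene 1: delta 35 -> dominant; still expressed at 15% in B -> not specific
    # gene 2: 100% vs 0%: dominant and specific
    mean = pd.DataFrame({"A": [2.1, 4.0, 5.0], "B": [1.0, 2.0, 0.0]})
    pct = pd.DataFrame({"A": [50.0, 60.0, 100.0], "B": [30.0, 15.0, 0.0]})
    de = _craft_de(mean, pct)
    dom = call_dominant_specific(de, targets=["A"])
    frame = dom.calls["A"]
    assert list(frame["upregulated"]) == [True, True, True]
    assert list(frame["dominant"]) == [False, True, True]
    assert list(frame["specific"]) == [False, False, True]


def test_group_dominance_requires_every_pair():
    types = ["C", "G", "T", "S", "L", "FSC", "E"]
    # gene 0: 40% in every HPC type, < 5% outside -> HPC dominant and specific
    # gene 1: only 4 of 5 HPC types expressing -> not an HPC-group call
    mean = pd.DataFrame(
        {t: [3.0 if t in "CGTSL" else 0.1, 3.0 if t in "CGTS" else 0.1] for t in types}
    )
    pct = pd.DataFrame(
        {t: [40.0 if t in "CGTSL" else 2.0, 40.0 if t in "CGTS" else 2.0] for t in types}
    )
    de = _craft_de(mean, pct)
    dom = call_dominant_specific(de, targets=["HPC"])
    frame = dom.calls["HPC"]
    assert frame["dominant"][0] and frame["specific"][0]
    assert not frame["dominant"][1]
    with pytest.raises(ValueError, match="unknown target"):
        call_dominant_specific(de, targets=["NOPE"])


def test_sex_dominant_genes_are_recovered(nine_type, nine_type_norm, nine_type_calls):
    _, matrix, truth = nine_type
    result = sex_de(
        nine_type_norm, nine_type_calls, truth.cell_type, truth.cells["sex"].to_numpy()
    )
    symbols = list(matrix.gene_symbols)
    lf = result.calls[("L", "F")]
    for g in ("Cyp2c12", "Prlr-f1", "Sult1e1"):
        i = symbols.index(g)
        assert lf["dominant"][i], g
        assert lf["specific"][i], g
    gm = result.calls[("G", "M")]
    for g in ("Eif2s3y", "Ddx3y"):
        assert gm["dominant"][symbols.index(g)], g
    # genes with no planted sex effect are called at a negligible rate
    null = np.array([s.startswith("Gene") for s in matrix.gene_symbols])
    rate = np.mean(
        [frame["upregulated"].to_numpy()[null].mean() for frame in result.calls.values()]
    )
    assert rate <= 0.005
    for frame in result.calls.values():
        assert not (frame["specific"] & ~frame["dominant"]).any()
        assert not (frame["dominant"] & ~frame["upregulated"]).any()


def test_de_requires_two_types(nine_type_norm, nine_type_calls):
    with pytest.raises(ValueError):
        de_tests(nine_type_norm, nine_type_calls, np.array(["A"] * nine_type_norm.n_cells))
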