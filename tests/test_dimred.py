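import numpy as np
import pytest

import pitsc
from pitsc.dimred import (
    _standardize_clamp,
    n_significant_pcs,
    permute_gene_counts,
    reduce,
    select_hvg,
    embed2d,
)
from pitsc.io import NormalizedMatrix
from pitsc.synthetic import SyntheticConfig, generate_dataset


def make_norm(E):
    E = np.asarray(E, dtype=float)
    return NormalizedMatrix(E=E, log_expr=np.log10(E + 1.0), median_total=1.0)


def noise_config(seed, n_genes=300, n_cells=400):
    """No cell structure: one type, no programs, constant library size,
    Poisson-limit dispersion."""
    return SyntheticConfig(
        n_genes=n_genes,
        n_cells_per_type={"A": {"F": n_cells // 2, "M": n_cells - n_cells // 2}},
        marker_program={},
        library_size_log_params=(0.0, 0.0),
        nb_dispersion=1e6,
        ambient_fraction=0.0,
        mito_gene_count=0,
        doublet_rate=0.0,
        seed=seed,
    )


def programs_config(seed=0, fold=10.0, n_cells=150):
    """Three disjoint 20-gene programs over a shared background type: three
    independent structure dimensions after centering."""
    return SyntheticConfig(
        n_genes=300,
        n_cells_per_type={t: {"F": n_cells // 2, "M": n_cells // 2} for t in "ABCD"},
        marker_program={
            "A": {g: fold for g in range(20)},
            "B": {g: fold for g in range(20, 40)},
            "C": {g: fold for g in range(40, 60)},
        },
        baseline_mean_override={g: 0.5 for g in range(60)},
        library_size_log_params=(0.0, 0.0),
        ambient_fraction=0.0,
        mito_gene_count=0,
        doublet_rate=0.0,
        seed=seed,
    )


def test_poisson_like_gene_has_zero_dispersion():
    # sample variance equals the mean: phi = (s^2 - m)/m^2 = 0
    E = np.tile([0.0, 1.0, 2.0], (40, 1))
    hvg = select_hvg(make_norm(E), n_top=10, min_cells=1)
    np.testing.assert_allclose(hvg.dispersion, 0.0, atol=1e-12)


def test_zero_mad_bin_gets_zero_normalized_dispersion(rng):
    E = np.tile(rng.poisson(3.0, 50).astype(float), (30, 1))  # identical genes
    hvg = select_hvg(make_norm(E), n_top=5, min_cells=1, n_bins=3)
    np.testing.assert_allclose(hvg.norm_dispersion, 0.0)


def test_planted_markers_outrank_matched_mean_baseline_genes():
    # 20 bimodal markers among 400 baseline genes whose lognormal means span
    # the markers' range: the markers must dominate the selected set
    # marker overall means spread through the dense part of the baseline
    # mean distribution, so every marker competes against matched-mean
    # unimodal genes within its bin
    folds = {g: 5.0 + (g % 5) for g in range(20)}
    base = {g: 2 * (0.6 + 0.08 * g) / (folds[g] + 1) for g in range(20)}
    config = SyntheticConfig(
        n_genes=420,
        n_cells_per_type={"A": {"F": 150, "M": 150}, "B": {"F": 150, "M": 150}},
        marker_program={
            "A": {g: folds[g] for g in range(10)},
            "B": {g: folds[g] for g in range(10, 20)},
        },
        baseline_mean_override=base,
        baseline_mean_log_params=(np.log(0.5), 1.5),
        ambient_fraction=0.0,
        mito_gene_count=0,
        doublet_rate=0.0,
        seed=11,
    )
    matrix, truth = generate_dataset(config)
    norm = pitsc.normalize(matrix)
    hvg = select_hvg(norm, n_top=40, min_cells=30)
    marker = np.array(["marker" in r for r in truth.genes["role"]])
    assert hvg.selected[marker].mean() >= 0.90


def test_hvg_selection_is_order_invariant(nine_type_norm):
    hvg = select_hvg(nine_type_norm, n_top=50)
    rng = np.random.default_rng(3)
    cperm = rng.permutation(nine_type_norm.n_cells)
    gperm = rng.permutation(nine_type_norm.n_genes)
    shuffled = NormalizedMatrix(
        E=nine_type_norm.E[np.ix_(gperm, cperm)],
        log_expr=nine_type_norm.log_expr[np.ix_(gperm, cperm)],
        median_total=nine_type_norm.median_total,
    )
    hvg2 = select_hvg(shuffled, n_top=50)
    assert np.array_equal(hvg2.selected, hvg.selected[gperm])


def test_standardized_values_are_clamped(rng):
    values = np.zeros((1, 500))
    values[0, 0] = 1e6  # extreme outlier: z-score far above 10
    X = _standardize_clamp(values, np.array([True]))
    assert X.max() == 10.0
    assert X.min() >= -10.0


def test_identical_cells_get_identical_scores(rng):
    E = rng.lognormal(0.0, 1.0, (50, 80))
    E[:, 1] = E[:, 0]
    norm = make_norm(E)
    hvg = select_hvg(norm, n_top=30, min_cells=1)
    pcs = reduce(norm, hvg, n_pc=10)
    np.testing.assert_allclose(pcs.scores[0], pcs.scores[1], atol=1e-9)
    assert (np.diff(pcs.singular_values) <= 1e-9).all()


def test_reconstruction_error_is_nonincreasing_in_rank(rng):
    E = rng.lognormal(0.0, 1.0, (60, 120))
    norm = make_norm(E)
    hvg = select_hvg(norm, n_top=50, min_cells=1)
    X = _standardize_clamp(norm.log_expr, hvg.selected)
    residuals = []
    for n_pc in (5, 10, 20):
        pcs = reduce(norm, hvg, n_pc=n_pc)
        residuals.append(np.linalg.norm(X - pcs.scores @ pcs.loadings.T))
    assert residuals[0] >= residuals[1] >= residuals[2]


def test_permutation_preserves_gene_marginals(rng):
    dense = rng.poisson(2.0, (30, 50))
    perm = permute_gene_counts(dense.copy(), rng)
    for g in range(30):
        assert np.array_equal(np.sort(perm[g]), np.sort(dense[g]))
    assert not np.array_equal(perm, dense)


def test_pure_noise_has_no_significant_pcs():
    zeros = 0
    for seed in range(5):
        matrix, _ = generate_dataset(noise_config(seed))
        norm = pitsc.normalize(matrix)
        hvg = select_hvg(norm, n_top=200, min_cells=10)
        n_sig = n_significant_pcs(matrix, hvg, n_pc=10, n_reps=20, seed=seed)
        zeros += n_sig == 0
    assert zeros >= 4


def test_three_planted_programs_give_at_least_three_pcs():
    matrix, _ = generate_dataset(programs_config(seed=1))
    norm = pitsc.normalize(matrix)
    hvg = select_hvg(norm, n_top=200, min_cells=10)
    assert n_significant_pcs(matrix, hvg, n_pc=20, n_reps=20, seed=0) >= 3


def test_single_rep_threshold_and_monotonicity():
    matrix, _ = generate_dataset(programs_config(seed=2, n_cells=100))
    norm = pitsc.normalize(matrix)
    hvg = select_hvg(norm, n_top=150, min_cells=10)
    obs = reduce(norm, hvg, n_pc=15)
    n1 = n_significant_pcs(matrix, hvg, n_pc=15, n_reps=1, seed=0, observed=obs)
    n20 = n_significant_pcs(matrix, hvg, n_pc=15, n_reps=20, seed=0, observed=obs)
    assert n20 <= n1  # the max over more repetitions can only grow


def test_embedding_separates_planted_types():
    from sklearn.metrics import silhouette_score

    matrix, truth = generate_dataset(programs_config(seed=3, n_cells=120))
    norm = pitsc.normalize(matrix)
    hvg = select_hvg(norm, n_top=150, min_cells=10)
    pcs = reduce(norm, hvg, n_pc=10)
    pcs.n_significant = 4
    emb = embed2d(pcs, perplexity=30, n_iter=260, seed=0)
    emb2 = embed2d(pcs, perplexity=30, n_iter=260, seed=0)
    np.testing.assert_allclose(emb, emb2)  # deterministic given seed
    assert silhouette_score(emb, truth.cell_type[: len(emb)]) > 0.2
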