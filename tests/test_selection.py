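"""L0 sparse weights, feature ranking and the forward subset search."""
import numpy as np
import pytest

from ptcrad.phantoms import generate_feature_table
from ptcrad.selection import (
    SubsetSearchTrace,
    fit_sparse_weights,
    forward_search,
    rank_features,
    rank_order,
    standardize_columns,
)

from oracles import exhaustive_l0_objective


def _sparse_instance(seed, m=16, p=10, noise=0.1):
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((m, p))
    F, _, _ = standardize_columns(F)
    k = int(rng.integers(1, 4))
    idx = rng.choice(p, k, replace=False)
    w = rng.uniform(1, 2, k) * rng.choice([-1, 1], k)
    y = F[:, idx] @ w + noise * rng.standard_normal(m)
    return F, y, idx


class TestFitSparseWeights:
    def test_perfect_predictor_ranked_first(self):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((40, 8))
        F, _, _ = standardize_columns(F)
        y = F[:, 3].copy()
        model = fit_sparse_weights(F, y, gamma=0.1)
        assert model.ranking[0] == 3

    def test_matches_exhaustive_oracle_small_instances(self):
        for seed in range(300, 320):
            F, y, _ = _sparse_instance(seed)
            model = fit_sparse_weights(F, y, gamma=0.1)
            oracle = exhaustive_l0_objective(F, y, 0.1)
            assert abs(model.objective - oracle) < 1e-9, seed

    def test_fixed_small_sample_instance_matches_oracle(self):
        # the hard regime: as many features as samples + 2
        F, y, _ = _sparse_instance(101, m=8, p=10)
        model = fit_sparse_weights(F, y, gamma=0.1)
        assert abs(model.objective - exhaustive_l0_objective(F, y, 0.1)) < 1e-9

    def test_huge_gamma_gives_zero_weights(self):
        F, y, _ = _sparse_instance(1)
        model = fit_sparse_weights(F, y, gamma=1e9)
        assert np.all(model.w == 0)
        assert model.objective == pytest.approx(float(y @ y))

    def test_zero_variance_column_excluded_with_warning(self):
        F, y, _ = _sparse_instance(2)
        F[:, 4] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_sparse_weights(F, y, gamma=0.1)
        assert model.w[4] == 0.0
        assert 4 in model.excluded


class TestRanking:
    def test_descending_absolute_value(self):
        order = rank_order(np.array([0.0, 3.0, -5.0]))
        assert order.tolist() == [2, 1, 0]

    def test_tie_rule_lower_index_first(self):
        order = rank_order(np.array([0.0, 2.0, 0.0, -2.0, 0.0]))
        assert order.tolist() == [1, 3, 0, 2, 4]

    def test_ranking_is_permutation(self):
        F, y, _ = _sparse_instance(5, p=12)
        model = fit_sparse_weights(F, y, gamma=0.1)
        assert sorted(rank_features(model).tolist()) == list(range(12))

    def test_planted_features_in_top_ten(self):
        ps = generate_feature_table(200, 100, 5, 2.0, seed=7)
        X, _, _ = standardize_columns(ps.matrix)
        model = fit_sparse_weights(X, ps.features.encoded_labels(), gamma=0.1)
        top10 = set(model.ranking[:10].tolist())
        assert ps.informative_indices <= top10

    def test_rank_monotone_in_effect_size(self):
        """A stronger planted column never ranks lower (fixed seed)."""
        ranks = []
        for effect in (0.5, 1.0, 2.0, 4.0):
            rng = np.random.default_rng(9)
            X = rng.standard_normal((120, 30))
            y = np.where(np.arange(120) % 2 == 0, 1.0, -1.0)
            X[:, 0] += 0.5 * effect * y
            Xs, _, _ = standardize_columns(X)
            model = fit_sparse_weights(Xs, y, gamma=0.1)
            ranks.append(int(np.flatnonzero(model.ranking == 0)[0]))
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))


class TestForwardSearch:
    def test_trace_covers_5_to_100(self):
        ps = generate_feature_table(120, 120, 5, 3.0, seed=3)
        X, _, _ = standardize_columns(ps.matrix)
        model = fit_sparse_weights(X, ps.features.encoded_labels(), gamma=0.1)
        trace = forward_search(
            ps.matrix, ps.labels.to_numpy(), model.ranking,
            size_range=(5, 100), cv_folds=5, seed=1,
        )
        assert len(trace.subset_sizes) == 96
        assert trace.subset_sizes[0] == 5 and trace.subset_sizes[-1] == 100
        assert np.all(np.diff(trace.subset_sizes) == 1)
        assert trace.cv_accuracy[trace.subset_sizes == trace.best_size][0] == trace.cv_accuracy.max()

    def test_separable_table_reaches_accuracy_one(self):
        ps = generate_feature_table(80, 30, 4, 6.0, seed=13)
        X, _, _ = standardize_columns(ps.matrix)
        model = fit_sparse_weights(X, ps.features.encoded_labels(), gamma=0.1)
        trace = forward_search(
            ps.matrix, ps.labels.to_numpy(), model.ranking,
            size_range=(5, 30), cv_folds=5, seed=1,
        )
        assert trace.cv_accuracy.max() == 1.0

    def test_null_table_accuracy_near_half(self):
        ps = generate_feature_table(100, 20, 0, 0.0, seed=17)
        X, _, _ = standardize_columns(ps.matrix)
        model = fit_sparse_weights(X, ps.features.encoded_labels(), gamma=0.1)
        trace = forward_search(
            ps.matrix, ps.labels.to_numpy(), model.ranking,
            size_range=(5, 20), cv_folds=5, seed=1,
        )
        # best-of-16 maximum of null accuracies: allow a generous band
        band = 2.58 * np.sqrt(0.25 / 100)
        assert trace.cv_accuracy.mean() == pytest.approx(0.5, abs=2 * band)

    def test_deterministic_under_fixed_seed(self):
        ps = generate_feature_table(60, 15, 2, 2.0, seed=23)
        X, _, _ = standardize_columns(ps.matrix)
        model = fit_sparse_weights(X, ps.features.encoded_labels(), gamma=0.1)
        kw = dict(size_range=(5, 15), cv_folds=5, seed=4)
        t1 = forward_search(ps.matrix, ps.labels.to_numpy(), model.ranking, **kw)
        t2 = forward_search(ps.matrix, ps.labels.to_numpy(), model.ranking, **kw)
        np.testing.assert_array_equal(t1.cv_accuracy, t2.cv_accuracy)
        assert t1.best_size == t2.best_size

    def test_fewer_than_five_features_warns(self):
        ps = generate_feature_table(40, 3, 1, 3.0, seed=29)
        X, _, _ = standardize_columns(ps.matrix)
        model = fit_sparse_weights(X, ps.features.encoded_labels(), gamma=0.1)
        with pytest.warns(UserWarning, match="available"):
            trace = forward_search(
                ps.matrix, ps.labels.to_numpy(), model.ranking,
                size_range=(5, 3), cv_folds=4, seed=0,
            )
        assert trace.subset_sizes.tolist() == [1, 2, 3]
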