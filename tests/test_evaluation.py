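"""Metric panel, DeLong comparison, screening, clustering and the split."""
import numpy as np
import pytest
from scipy import stats

from ptcrad.containers import AGGRESSIVE, NON_AGGRESSIVE, FeatureMatrix
from ptcrad.evaluation import (
    clopper_pearson,
    cluster_screen,
    delong_compare,
    metric_panel,
    split_cohort,
    split_indices,
    ttest_screen,
)
from ptcrad.phantoms import generate_feature_table

from oracles import auc_pair_count

POS, NEG = AGGRESSIVE, NON_AGGRESSIVE


def _labels(*flags):
    return np.array([POS if f else NEG for f in flags])


class TestMetricPanel:
    def test_perfect_scores(self):
        labels = _labels(1, 1, 0, 0)
        rep = metric_panel(labels, [0.9, 0.8, 0.2, 0.1], labels)
        assert rep.auc == 1.0
        assert rep.acc == rep.sen == rep.spe == 1.0

    def test_hand_computed_example(self):
        # 4 positive-negative score pairs, 3 concordant -> AUC 0.75
        labels = _labels(1, 1, 0, 0)
        scores = [0.9, 0.4, 0.6, 0.1]
        predictions = _labels(1, 0, 1, 0)
        rep = metric_panel(labels, scores, predictions)
        assert rep.auc == 0.75
        assert rep.acc == 0.5
        assert rep.sen == 0.5
        assert rep.spe == 0.5

    def test_anti_perfect_scores(self):
        labels = _labels(1, 1, 0, 0)
        rep = metric_panel(labels, [0.1, 0.2, 0.8, 0.9], labels)
        assert rep.auc == 0.0

    def test_confusion_identities_on_random_predictions(self):
        rng = np.random.default_rng(0)
        labels = _labels(*(rng.random(60) < 0.5))
        pred = _labels(*(rng.random(60) < 0.5))
        scores = rng.normal(size=60)
        rep = metric_panel(labels, scores, pred)
        n = rep.tp + rep.fp + rep.tn + rep.fn
        assert n == 60
        assert rep.acc == pytest.approx((rep.tp + rep.tn) / n)
        assert rep.sen == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.spe == pytest.approx(rep.tn / (rep.tn + rep.fp))
        assert rep.ppv == pytest.approx(rep.tp / (rep.tp + rep.fp))
        assert rep.npv == pytest.approx(rep.tn / (rep.tn + rep.fn))
        for v, ci in [(rep.acc, rep.acc_ci), (rep.sen, rep.sen_ci), (rep.auc, rep.auc_ci)]:
            assert ci[0] <= v <= ci[1]

    def test_auc_matches_pair_count_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            labels = _labels(*(rng.random(n) < 0.5))
            if len(set(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            rep = metric_panel(labels, scores, labels)
            assert rep.auc == pytest.approx(auc_pair_count(labels, scores, POS))

    def test_single_class_rejected(self):
        labels = _labels(1, 1, 1)
        with pytest.raises(ValueError, match="single-class"):
            metric_panel(labels, [0.1, 0.2, 0.3], labels)

    def test_table_row_format(self):
        labels = _labels(1, 1, 0, 0)
        rep = metric_panel(labels, [0.9, 0.8, 0.2, 0.1], labels, model_name="DWI")
        row = rep.to_row()
        assert set(row) == {"Models", "AUC", "ACC", "SEN", "SPE", "PPV", "NPV"}
        assert row["Models"] == "DWI"
        assert "[" in row["AUC"] and "]" in row["AUC"]


class TestClopperPearson:
    def test_exact_coverage_edges(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_known_value(self):
        # 8/10: standard exact interval ~ (0.444, 0.975)
        lo, hi = clopper_pearson(8, 10)
        assert lo == pytest.approx(0.4439, abs=1e-3)
        assert hi == pytest.approx(0.9748, abs=1e-3)


class TestDeLong:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(2)
        labels = _labels(*(rng.random(40) < 0.5))
        s = rng.normal(size=40)
        p, diff = delong_compare(labels, s, s)
        assert p == 1.0 and diff == 0.0

    def test_monotone_transform_p_one(self):
        rng = np.random.default_rng(3)
        labels = _labels(*(rng.random(40) < 0.5))
        s = rng.normal(size=40)
        p, diff = delong_compare(labels, s, np.exp(s))
        assert p == 1.0 and diff == pytest.approx(0.0)

    def test_clearly_different_scorings_reject(self):
        rng = np.random.default_rng(4)
        y = np.repeat([1, 0], 100)
        labels = _labels(*y)
        good = y + 0.3 * rng.normal(size=200)
        noise = rng.normal(size=200)
        p, diff = delong_compare(labels, good, noise)
        assert diff > 0.2
        assert p < 0.01

    def test_type_one_error_calibrated(self):
        """Under an equal-AUC null the 5% test rejects ~5% of the time."""
        rng = np.random.default_rng(5)
        n, reps = 200, 1000
        rejections = 0
        y = np.repeat([1, 0], n // 2)
        labels = _labels(*y)
        for _ in range(reps):
            latent = y + rng.normal(size=n)
            a = latent + 0.5 * rng.normal(size=n)
            b = latent + 0.5 * rng.normal(size=n)
            p, _ = delong_compare(labels, a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestTtestScreen:
    def _fm(self, X, y):
        import pandas as pd

        ids = [f"c{i}" for i in range(len(y))]
        return FeatureMatrix(
            pd.DataFrame(X, index=ids), pd.Series(_labels(*y), index=ids)
        )

    def test_null_pass_rate_binomial(self):
        ps = generate_feature_table(200, 1000, 0, 0.0, seed=6)
        selected, table = ttest_screen(ps.features, alpha=0.05)
        rate = len(selected) / 1000
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_strong_effect_all_pass(self):
        """Effect 3 at n=200: power > 0.999 at alpha 0.001."""
        ps = generate_feature_table(200, 50, 10, 3.0, seed=7)
        selected, _ = ttest_screen(ps.features, alpha=0.001)
        names = [ps.features.feature_names[j] for j in ps.informative_indices]
        assert set(names) <= set(selected)

    def test_alpha_one_returns_everything(self):
        ps = generate_feature_table(50, 20, 0, 0.0, seed=8)
        selected, _ = ttest_screen(ps.features, alpha=1.0001)
        assert len(selected) == 20

    def test_zero_variance_column_p_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 3))
        X[:, 1] = 4.2
        y = (np.arange(30) % 2).astype(bool)
        fm = self._fm(X, y)
        _, table = ttest_screen(fm, alpha=0.5)
        assert table.iloc[1] == 1.0


class TestClusterScreen:
    def test_separated_blobs_fraction_one(self):
        rng = np.random.default_rng(10)
        X = np.vstack([
            rng.normal(0, 0.3, size=(30, 4)),
            rng.normal(5, 0.3, size=(30, 4)),
        ])
        y = [0] * 30 + [1] * 30
        fm = TestTtestScreen()._fm(X, y)
        res = cluster_screen(fm)
        assert res.fraction_correct == 1.0
        assert res.confusion.sum() == 60

    def test_label_feature_fraction_one(self):
        y = (np.arange(40) % 2).astype(bool)
        X = y.astype(float).reshape(-1, 1)
        fm = TestTtestScreen()._fm(X, y)
        assert cluster_screen(fm).fraction_correct == 1.0

    def test_shuffled_labels_within_permutation_null(self):
        rng = np.random.default_rng(11)
        X = np.vstack([
            rng.normal(0, 0.3, size=(30, 4)),
            rng.normal(5, 0.3, size=(30, 4)),
        ])
        y = rng.permutation([0] * 30 + [1] * 30)  # signal destroyed
        fm = TestTtestScreen()._fm(X, y)
        frac = cluster_screen(fm).fraction_correct
        # permutation null of best-of-two-mappings agreement between a fixed
        # 30/30 partition and shuffled labels: hypergeometric; 95% band
        sims = []
        rng2 = np.random.default_rng(12)
        part = np.array([0] * 30 + [1] * 30)
        for _ in range(1000):
            yy = rng2.permutation(part)
            agree = (yy == part).mean()
            sims.append(max(agree, 1 - agree))
        assert frac <= np.quantile(sims, 0.975) + 1e-9

    def test_zero_features_rejected(self):
        import pandas as pd

        fm = FeatureMatrix(
            pd.DataFrame(index=["a", "b", "c", "d"]),
            pd.Series(_labels(1, 1, 0, 0), index=["a", "b", "c", "d"]),
        )
        with pytest.raises(ValueError, match="alpha"):
            cluster_screen(fm)


class TestSplit:
    def test_107_cases_split_71_36(self):
        labels = np.array([POS] * 51 + [NEG] * 56)
        tr, te = split_indices(labels, 71 / 107, seed=0)
        assert len(tr) == 71 and len(te) == 36

    def test_default_two_thirds_on_107(self):
        labels = np.array([POS] * 51 + [NEG] * 56)
        tr, te = split_indices(labels, 2 / 3, seed=0)
        assert len(tr) == 71 and len(te) == 36

    def test_seed_stability_and_determinism(self):
        labels = np.array([POS] * 51 + [NEG] * 56)
        a = split_indices(labels, 2 / 3, seed=42)
        b = split_indices(labels, 2 / 3, seed=42)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        c = split_indices(labels, 2 / 3, seed=43)
        assert not np.array_equal(a[0], c[0])

    def test_stratification_proportions(self):
        labels = np.array([POS] * 51 + [NEG] * 56)
        tr, te = split_indices(labels, 2 / 3, seed=1)
        for cls, total in ((POS, 51), (NEG, 56)):
            k_tr = (labels[tr] == cls).sum()
            assert abs(k_tr - total * 2 / 3) <= 1

    def test_split_cohort_objects(self, small_cohort):
        tr, te = split_cohort(small_cohort, 0.5, seed=0)
        assert len(tr) == 2 and len(te) == 2
        ids = {c.case_id for c in tr} | {c.case_id for c in te}
        assert len(ids) == 4
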