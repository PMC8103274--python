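"""Statistical layer: CID labels, t-tests, ROC/DeLong, SVM models, logistic."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from vrmotor import (
    compare_auc,
    fit_logistic,
    fit_svm_classifier,
    fit_svm_regressor,
    label_cid,
    laterality_ttest,
    mse,
    roc_auc,
)
from vrmotor.errors import AnalysisError


def pair_count_auc(scores, labels):
    """Exhaustive positive/negative pair counting, ties worth one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, labels):
    """Direct enumeration of placement values and their (co)variances."""
    labels = np.asarray(labels, bool)

    def placements(scores):
        pos = scores[labels]
        neg = scores[~labels]
        v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
        v01 = np.array([np.mean((pos > n) + 0.5 * (pos == n)) for n in neg])
        return v10, v01

    v10a, v01a = placements(np.asarray(scores_a, float))
    v10b, v01b = placements(np.asarray(scores_b, float))

    def cov(x, y):
        return float(np.sum((x - x.mean()) * (y - y.mean())) / (len(x) - 1))

    m, n = len(v10a), len(v01a)
    return {
        "auc_a": v10a.mean(),
        "auc_b": v10b.mean(),
        "var_a": cov(v10a, v10a) / m + cov(v01a, v01a) / n,
        "var_b": cov(v10b, v10b) / m + cov(v01b, v01b) / n,
        "cov_ab": cov(v10a, v10b) / m + cov(v01a, v01b) / n,
    }


class TestCid:
    @pytest.mark.parametrize("score,expected", [(0, False), (10, False), (11, True), (132, True)])
    def test_strict_threshold(self, score, expected):
        assert label_cid(score) is expected

    @pytest.mark.parametrize("score", [-1, 133])
    def test_out_of_range(self, score):
        with pytest.raises(AnalysisError):
            label_cid(score)


class TestLateralityTTest:
    def test_identical_paired_vectors(self):
        res = laterality_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], mode="paired")
        assert res.t == 0.0 and res.p == 1.0

    def test_two_sample_matches_closed_form(self):
        left = np.array([4.1, 5.2, 6.3, 5.8])
        right = np.array([3.9, 4.2, 4.8])
        nl, nr = len(left), len(right)
        sp2 = ((nl - 1) * left.var(ddof=1) + (nr - 1) * right.var(ddof=1)) / (nl + nr - 2)
        t_expected = (left.mean() - right.mean()) / math.sqrt(sp2 * (1 / nl + 1 / nr))
        res = laterality_ttest(left, right)
        assert res.t == pytest.approx(t_expected, rel=1e-12)
        from scipy.stats import t as tdist

        assert res.p == pytest.approx(2 * tdist.sf(abs(t_expected), nl + nr - 2), rel=1e-12)

    def test_constant_shift_paired_is_degenerate(self):
        res = laterality_ttest([1.0, 2.0, 3.0], [0.5, 1.5, 2.5], mode="paired")
        assert res.degenerate and res.p == 0.0 and res.t > 0

    def test_insufficient_n(self):
        with pytest.raises(AnalysisError):
            laterality_ttest([1.0], [1.0, 2.0])


class TestRocAuc:
    def test_perfect_ranking(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == 1.0
        assert res.fpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert roc_auc(-scores, labels).auc == pytest.approx(
            1 - roc_auc(scores, labels).auc
        )

    def test_tied_toy_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.4, 0.6, 0.7, 0.7]
        labels = [0, 0, 1, 0, 1, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(pair_count_auc(scores, labels))

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.linspace(0, 1, 7), n)  # force ties
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_roc_is_monotone_staircase(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)


class TestCompareAuc:
    def test_identical_scores_give_p_one(self):
        scores = [0.2, 0.4, 0.6, 0.8, 0.3, 0.7]
        labels = [0, 0, 1, 1, 0, 1]
        res = compare_auc(scores, scores, labels)
        assert res.diff == 0.0 and res.p == 1.0

    def test_placement_variances_match_enumeration_at_n10(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
            rng.shuffle(labels)
            a = rng.normal(size=10) + labels
            b = rng.choice(np.linspace(0, 1, 5), 10)
            res = compare_auc(a, b, labels)
            ref = delong_oracle(a, b, labels)
            assert res.auc_a == pytest.approx(ref["auc_a"])
            assert res.var_a == pytest.approx(ref["var_a"], rel=1e-10)
            assert res.var_b == pytest.approx(ref["var_b"], rel=1e-10)
            assert res.cov_ab == pytest.approx(ref["cov_ab"], rel=1e-10, abs=1e-15)

    def test_power_against_uninformative_competitor(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 50)
            informative = labels + rng.normal(0, 0.5, 100)
            noise = rng.normal(size=100)
            if compare_auc(informative, noise, labels).p < 0.05:
                hits += 1
        assert hits >= 45  # >= 90% of seeds

    def test_length_mismatch(self):
        with pytest.raises(AnalysisError):
            compare_auc([0.1, 0.2], [0.1], [0, 1])


class TestSvmClassifier:
    def separable_toy(self):
        X = np.array(
            [[-2, -2], [-1.5, -1], [-1, -2], [-2, -1], [2, 2], [1.5, 1], [1, 2], [2, 1]],
            dtype=float,
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        return X, y

    def test_separable_resubstitution_auc_one(self):
        X, y = self.separable_toy()
        ev = fit_svm_classifier(X, y, cv_folds=0)
        assert ev.auc == 1.0
        assert np.all((ev.scores >= 0) & (ev.scores <= 1))

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = fit_svm_classifier(X, y, cv_folds=5, seed=11)
        b = fit_svm_classifier(X, y, cv_folds=5, seed=11)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.folds, b.folds)

    def test_single_class_rejected(self):
        with pytest.raises(AnalysisError):
            fit_svm_classifier(np.zeros((5, 2)) + np.arange(5)[:, None], [1] * 5)

    def test_null_features_give_chance_level_cv_auc(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 4))
            y = np.repeat([0, 1], 100)
            aucs.append(fit_svm_classifier(X, y, cv_folds=5, seed=seed).auc)
        assert 0.42 <= np.mean(aucs) <= 0.58


class TestLogistic:
    def test_two_by_two_table_recovers_odds_ratio(self):
        x = np.array([1] * 10 + [0] * 10, dtype=float)
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(16.0, rel=1e-4)
        assert fit.table.loc["x", "beta"] == pytest.approx(math.log(16.0), rel=1e-4)
        assert not fit.separation

    def test_or_equals_exp_beta_everywhere(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=80), "b": rng.integers(0, 2, 80).astype(float)})
        y = (X["a"] + rng.normal(0, 1, 80) > 0).astype(int)
        fit = fit_logistic(X, y)
        assert np.allclose(fit.table["odds_ratio"], np.exp(fit.table["beta"]), rtol=1e-12)

    def test_independent_predictor_is_null(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"noise": rng.normal(size=1000)})
        y = rng.integers(0, 2, 1000)
        fit = fit_logistic(X, y)
        assert fit.table.loc["noise", "odds_ratio"] == pytest.approx(1.0, abs=0.2)
        assert fit.table.loc["noise", "p_value"] > 0.05

    def test_constant_column_rejected(self):
        with pytest.raises(AnalysisError):
            fit_logistic(pd.DataFrame({"c": np.ones(20)}), np.tile([0, 1], 10))

    def test_separation_flagged_not_raised(self):
        x = np.linspace(-1, 1, 30)
        y = (x > 0).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.separation


class TestSvmRegressor:
    def test_mse_fixed_vectors(self):
        assert mse([1, 2, 3], [1, 2, 5]) == pytest.approx(4 / 3)

    def test_noiseless_linear_target_recovered(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 1))
        y = 3.0 * X[:, 0] + 5.0
        ev = fit_svm_regressor(X, y, seed=0)
        assert ev.splits["test"].r_squared >= 0.99
        assert ev.splits["all"].r_squared >= 0.99

    def test_missing_rows_are_dropped(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        X.iloc[3, 0] = np.nan
        X.iloc[7, 1] = np.nan
        y = 2 * X["a"].fillna(0) + rng.normal(0, 0.1, 30) + 20
        ev = fit_svm_regressor(X, y, seed=1)
        assert ev.n_dropped_missing == 2
        assert len(ev.predictions) == 28

    def test_null_features_give_near_zero_test_r2(self):
        r2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(200, 5))
            y = rng.normal(20, 10, 200)
            r2s.append(fit_svm_regressor(X, y, seed=seed).splits["test"].r_squared)
        assert np.mean(r2s) <= 0.08

    def test_too_few_rows_rejected(self):
        with pytest.raises(AnalysisError):
            fit_svm_regressor(np.zeros((6, 2)) + np.arange(6)[:, None], np.arange(6.0))
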