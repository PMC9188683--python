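"""Metrics, resampling, feature selection, voting and the corrected t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ceusrad as cr
from ceusrad.bench import (
    ResamplingError,
    classification_metrics,
    smote_oversample,
)


class TestBalancedAccuracy:
    def test_perfect_classifier(self):
        assert cr.balanced_accuracy(10, 0, 5, 0) == 1.0

    def test_all_positive_prediction(self):
        """Predicting everything malignant: SENS 1, SPEC 0, bACC 0.5."""
        assert cr.balanced_accuracy(74, 0, 0, 13) == 0.5

    def test_worked_example(self):
        assert cr.balanced_accuracy(3, 1, 1, 1) == pytest.approx(0.625)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            cr.balanced_accuracy(0, 0, 3, 1)

    def test_bacc_is_mean_of_sens_spec(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            p = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            m = classification_metrics(y, p)
            assert m["bACC"] == pytest.approx(0.5 * (m["SENS"] + m["SPEC"]))


class TestResampling:
    def test_floor_arithmetic(self, rng):
        """10 benign / 55 malignant -> 27 benign, 38 malignant."""
        X = rng.standard_normal((65, 4))
        y = np.array([0] * 10 + [1] * 55)
        Xr, yr = cr.resample_training(X, y, seed=3)
        assert (yr == 0).sum() == 27
        assert (yr == 1).sum() == 38

    def test_balanced_input_only_undersampled(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.repeat([0, 1], 20)
        Xr, yr = cr.resample_training(X, y, seed=0)
        assert (yr == 0).sum() == 20          # already above the 0.5 ratio
        assert (yr == 1).sum() == 14

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((65, 4))
        y = np.array([0] * 10 + [1] * 55)
        a, _ = cr.resample_training(X, y, seed=7)
        b, _ = cr.resample_training(X, y, seed=7)
        assert np.array_equal(a, b)

    def test_synthetic_rows_are_interpolations(self, rng):
        X_min = rng.standard_normal((10, 2))
        syn = smote_oversample(X_min, 50, 5, np.random.default_rng(0))
        # every synthetic point lies within the minority bounding box
        assert np.all(syn >= X_min.min(axis=0) - 1e-12)
        assert np.all(syn <= X_min.max(axis=0) + 1e-12)

    def test_too_few_minority_rejected(self, rng):
        X = rng.standard_normal((60, 3))
        y = np.array([0] * 3 + [1] * 57)
        with pytest.raises(ResamplingError):
            cr.resample_training(X, y, seed=0)


class TestBackwardSFS:
    def test_separating_feature_survives(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 6))
        X[:, 3] = y * 4.0 + 0.1 * rng.standard_normal(n)
        model, _ = cr.default_models(0)["LR"]
        cols = cr.backward_sfs(model, X, y, n_target=1, seed=0)
        assert cols.tolist() == [3]

    def test_identity_when_target_equals_n(self, rng):
        X = rng.standard_normal((30, 4))
        y = rng.integers(0, 2, 30)
        model, _ = cr.default_models(0)["LR"]
        assert cr.backward_sfs(model, X, y, 4).tolist() == [0, 1, 2, 3]

    def test_duplicate_feature_dropped_first(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        sig = y * 3.0 + 0.1 * rng.standard_normal(n)
        X = np.column_stack([sig, sig.copy(), rng.standard_normal(n)])
        model, _ = cr.default_models(0)["LR"]
        cols = cr.backward_sfs(model, X, y, n_target=2, seed=0)
        assert 0 in cols or 1 in cols         # one informative copy kept
        assert not (0 in cols and 1 in cols)


class TestSoftVoting:
    class Stub:
        def __init__(self, p):
            self.p = p

        def predict_proba(self, X):
            return np.tile([1 - self.p, self.p], (len(X), 1))

    def test_agreeing_bases(self):
        svc = cr.SoftVotingClassifier([(self.Stub(0.9), np.array([0]))] * 3)
        X = np.zeros((4, 1))
        assert np.allclose(svc.predict_proba(X)[:, 1], 0.9)

    def test_tie_goes_malignant(self):
        svc = cr.SoftVotingClassifier([
            (self.Stub(0.6), np.array([0])), (self.Stub(0.4), np.array([0])),
        ])
        assert svc.predict(np.zeros((2, 1))).tolist() == [1, 1]

    def test_mean_below_half_is_benign(self):
        svc = cr.SoftVotingClassifier([
            (self.Stub(0.9), np.array([0])), (self.Stub(0.2), np.array([0])),
            (self.Stub(0.2), np.array([0])),
        ])
        assert svc.predict(np.zeros((1, 1))).tolist() == [0]

    def test_probability_outputs_required(self):
        class NoProba:
            def predict(self, X):
                return np.zeros(len(X))

        with pytest.raises(ValueError):
            cr.SoftVotingClassifier([(NoProba(), np.array([0]))])


class TestPermutationImportance:
    def test_unused_and_sole_features(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        X = np.column_stack([
            y * 4.0 + 0.05 * rng.standard_normal(n), rng.standard_normal(n),
        ])
        model, _ = cr.default_models(0)["LR"]
        model.fit(X, y)
        pfi = cr.permutation_importance(model, X, y, n_perm=10, seed=0)
        assert pfi[0] > 0.3
        assert abs(pfi[1]) < 0.05

    def test_redundant_pair_shares_importance(self, rng):
        n = 200
        y = np.repeat([0, 1], n // 2)
        sig = y * 4.0 + 0.05 * rng.standard_normal(n)
        X2 = np.column_stack([sig, sig + 0.01 * rng.standard_normal(n)])
        model, _ = cr.default_models(0)["LR"]
        model.fit(X2, y)
        pfi2 = cr.permutation_importance(model, X2, y, n_perm=10, seed=0)
        X1 = sig[:, None]
        model1, _ = cr.default_models(0)["LR"]
        model1.fit(X1, y)
        pfi1 = cr.permutation_importance(model1, X1, y, n_perm=10, seed=0)
        assert pfi2[0] < pfi1[0] and pfi2[1] < pfi1[0]


class TestCorrectedTTest:
    def test_identical_models_t_zero(self):
        p = np.array([0.8, 0.82, 0.78, 0.81])
        res = cr.corrected_t_test(p, p, 60, 20)
        assert res.t == 0 and not res.reject

    def test_antisymmetry(self, rng):
        a = 0.8 + 0.05 * rng.standard_normal(20)
        b = 0.7 + 0.05 * rng.standard_normal(20)
        r1 = cr.corrected_t_test(a, b, 60, 20)
        r2 = cr.corrected_t_test(b, a, 60, 20)
        assert r1.t == pytest.approx(-r2.t)

    def test_reduces_to_uncorrected_at_rho_zero(self, rng):
        a = 0.8 + 0.05 * rng.standard_normal(20)
        b = 0.75 + 0.05 * rng.standard_normal(20)
        res = cr.corrected_t_test(a, b, 60, 20, correction_ratio=0.0)
        ref = stats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_correction_shrinks_t(self, rng):
        a = 0.8 + 0.05 * rng.standard_normal(20)
        b = 0.75 + 0.05 * rng.standard_normal(20)
        t0 = cr.corrected_t_test(a, b, 60, 20, correction_ratio=0.0).t
        t1 = cr.corrected_t_test(a, b, 60, 20).t
        assert abs(t1) < abs(t0)

    def test_constant_nonzero_difference_degenerate(self):
        a = np.full(20, 0.9)
        b = np.full(20, 0.8)
        res = cr.corrected_t_test(a, b, 60, 20)
        assert res.degenerate and np.isinf(res.t) and res.t > 0


def make_separable_table(rng, n=48, n_feat=8):
    y = np.array([1] * (n * 2 // 3) + [0] * (n - n * 2 // 3))
    X = rng.standard_normal((n, n_feat))
    X[:, 0] += y * 5.0
    X[:, 1] -= y * 4.0
    cols = [f"f{i}" for i in range(n_feat)]
    return pd.DataFrame(X, columns=cols), y


@pytest.fixture(scope="module")
def small_models():
    full = cr.default_models(0)
    return {"LR": full["LR"], "kNN": full["kNN"]}


class TestNestedCV:
    def test_20_evaluations_and_metric_identity(self, rng, small_models):
        X, y = make_separable_table(rng)
        cfg = cr.CVConfig(seed=0, n_perm=3)
        report = cr.nested_cv(X, y, cfg, small_models)
        per_model = report.per_fold.groupby("model").size()
        assert (per_model == 20).all()
        ok = report.per_fold.dropna(subset=["bACC"])
        assert np.allclose(ok["bACC"], 0.5 * (ok["SENS"] + ok["SPEC"]))

    def test_separable_cohort_high_bacc(self, rng, small_models):
        X, y = make_separable_table(rng)
        report = cr.nested_cv(X, y, cr.CVConfig(seed=0, n_perm=3), small_models)
        assert report.metrics.loc["sVC", "bACC"] >= 0.9
        assert report.metrics.loc["Naive", "bACC"] == pytest.approx(0.5)
        assert report.metrics.loc["Naive", "SENS"] == pytest.approx(1.0)
        assert report.metrics.loc["Naive", "SPEC"] == pytest.approx(0.0)

    def test_sfs_reduces_features(self, rng, small_models):
        X, y = make_separable_table(rng, n_feat=6)
        cfg = cr.CVConfig(seed=0, n_perm=2, sfs_n_features=3)
        report = cr.nested_cv(X, y, cfg, small_models)
        freq = report.selection_frequency.loc["LR"]
        assert freq.sum() == pytest.approx(3.0)       # 3 features per fold
        assert freq["f0"] > 0.9                        # the separating feature


def test_feature_count_sweep_shape(rng):
    X, y = make_separable_table(rng, n=40, n_feat=5)
    models = {"LR": cr.default_models(0)["LR"]}
    cfg = cr.CVConfig(seed=0, repeats=2, n_perm=1)
    curve = cr.feature_count_sweep(X, y, [3, 5], cfg, models)
    assert set(curve["n_features"]) == {3, 5}
    assert ((curve["bACC_mean"] >= 0) & (curve["bACC_mean"] <= 1)).all()
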