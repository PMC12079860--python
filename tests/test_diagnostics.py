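"""ASAP score, detection-limit clipping, logistic models, ROC metrics."""
import numpy as np
import pandas as pd
import pytest

from meddx.diagnostics import (
    asap_score,
    clip_to_detection_limits,
    compare_auc,
    evaluate,
    fit_combined,
)
from meddx.stats import rank_auc


class TestAsapScore:
    def test_intercept_only_case(self):
        # age 0, female, AFP 1, PIVKA 1: every non-intercept term vanishes
        assert asap_score(0, 0, 1.0, 1.0) == pytest.approx(-6.836, abs=1e-12)

    def test_male_offset_is_exact(self):
        f = asap_score(50, 0, 7.0, 30.0)
        m = asap_score(50, 1, 7.0, 30.0)
        assert m - f == pytest.approx(0.989, abs=1e-12)

    def test_worked_example(self):
        # -6.836 + 0.042*65 + 0.989 + 1.841*1 + 0.949*2 = 0.622
        assert asap_score(65, 1, 10.0, 100.0) == pytest.approx(0.622, abs=1e-9)

    def test_strictly_increasing_in_continuous_inputs(self):
        base = asap_score(60, 1, 10.0, 100.0)
        assert asap_score(61, 1, 10.0, 100.0) > base
        assert asap_score(60, 1, 11.0, 100.0) > base
        assert asap_score(60, 1, 10.0, 110.0) > base

    def test_raw_zero_lifted_to_assay_floor(self):
        assert asap_score(60, 1, 0.0, 0.0) == asap_score(60, 1, 0.5, 5.0)


class TestClipping:
    @pytest.mark.parametrize(
        "afp,pivka,expected",
        [
            (3000.0, 100.0, (2000.0, 100.0)),
            (10.0, 1.0, (10.0, 5.0)),
            (10.0, 100.0, (10.0, 100.0)),
            (0.1, 100_000.0, (0.5, 75_000.0)),
        ],
    )
    def test_limits(self, afp, pivka, expected):
        assert clip_to_detection_limits(afp, pivka) == expected


class TestEvaluate:
    CASES = [0.9, 0.8, 0.4]
    CONTROLS = [0.7, 0.3, 0.2]

    def test_six_point_worked_set(self):
        scores = self.CASES + self.CONTROLS
        labels = [1, 1, 1, 0, 0, 0]
        res = evaluate(scores, labels, fixed_specificity=2 / 3)
        # exhaustive enumeration: smallest control threshold reaching
        # spec 2/3 is 0.3; all cases exceed it; 8 of 9 pairs concordant
        assert res.threshold == 0.3
        assert res.sensitivity == 1.0
        assert res.specificity == pytest.approx(2 / 3)
        assert res.auc == pytest.approx(8 / 9)

    def test_training_specificity_at_least_nominal(self):
        rng = np.random.default_rng(7)
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 60)])
        labels = np.r_[np.ones(40), np.zeros(60)]
        for s in (0.5, 0.8, 0.9, 0.95):
            assert evaluate(scores, labels, fixed_specificity=s).specificity >= s

    def test_carried_threshold_applied_unchanged(self):
        res = evaluate(self.CASES + self.CONTROLS, [1, 1, 1, 0, 0, 0], threshold=0.75)
        assert res.threshold == 0.75
        assert res.sensitivity == pytest.approx(2 / 3)

    def test_perfectly_separated(self):
        res = evaluate([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0], fixed_specificity=0.99)
        assert res.auc == 1.0 and res.sensitivity == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 2, 3], [1, 1, 1])

    def test_rank_auc_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = np.round(rng.normal(size=200), 1)  # ties on purpose
        labels = rng.integers(0, 2, 200)
        assert rank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestFitCombined:
    def cohort(self, seed, n=200, noise_feature=False):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        y = (latent + rng.normal(scale=0.8, size=n) > 0).astype(int)
        X = pd.DataFrame({"signal": latent})
        if noise_feature:
            X["noise"] = rng.normal(size=n)
        return X, y

    def test_informative_feature_positive_coefficient(self):
        X, y = self.cohort(1)
        fit = fit_combined(X, y)
        assert fit.params["signal"] > 0
        assert rank_auc(fit.decision_scores(X), y) > 0.8

    def test_aic_formula(self):
        X, y = self.cohort(2)
        fit = fit_combined(X, y)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.llf)

    def test_backward_eliminates_noise_feature(self):
        removed = 0
        for seed in range(60):
            X, y = self.cohort(100 + seed, noise_feature=True)
            fit = fit_combined(X, y, method="backward")
            removed += "noise" not in fit.features
        # expected removal probability ~0.95 at the p>0.05 rule
        assert removed / 60 >= 0.85

    def test_enter_and_backward_agree_when_all_informative(self):
        X, y = self.cohort(3)
        enter = fit_combined(X, y, method="enter")
        backward = fit_combined(X, y, method="backward")
        assert enter.features == backward.features

    def test_perfect_separation_flagged(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(15), np.ones(15)]})
        y = np.r_[np.zeros(15), np.ones(15)].astype(int)
        fit = fit_combined(X, y)
        assert fit.separated
        assert rank_auc(fit.decision_scores(X), y) == 1.0

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError):
            fit_combined(X, np.array([0, 1, 0]))


class TestCompareAuc:
    def test_model_vs_itself(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        out = compare_auc(s, s, y)
        assert out["p"] == 1.0

    def test_monotone_transform_has_equal_auc(self):
        rng = np.random.default_rng(10)
        s = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        out = compare_auc(s, np.exp(s), y)
        assert out["auc_a"] == pytest.approx(out["auc_b"], abs=1e-12)
        assert out["p"] == 1.0

    def test_type_one_error_near_nominal(self):
        # two independent equally-good models: ~5% rejections at 0.05
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 300
        for _ in range(reps):
            y = np.r_[np.ones(50), np.zeros(50)].astype(int)
            base = y * 1.0
            a = base + rng.normal(scale=2.0, size=100)
            b = base + rng.normal(scale=2.0, size=100)
            if compare_auc(a, b, y)["p"] < 0.05 and True:
                rejections += 1
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2], [1, 2, 3], [0, 1, 1])
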