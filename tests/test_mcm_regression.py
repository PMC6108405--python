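import math

import numpy as np
import pandas as pd
import pytest

from tlsmeta.errors import CollinearityError, ConvergenceError, ValidationError
from tlsmeta.mcm import (
    detect_complete_separation,
    diagnose_influence,
    fit_firth,
    fit_logistic,
    predict_classes,
    reduce_model,
)


def two_by_two(n11, n01, n10, n00):
    """(X, y) for the 2x2 table: cell counts (y, x)."""
    x = np.concatenate([np.ones(n11), np.ones(n01), np.zeros(n10), np.zeros(n00)])
    y = np.concatenate([np.ones(n11), np.zeros(n01), np.ones(n10), np.zeros(n00)])
    return x.reshape(-1, 1), y


def simulate_logistic(rng, beta0, beta, n):
    k = len(beta)
    X = rng.normal(size=(n, k))
    p = 1 / (1 + np.exp(-(beta0 + X @ np.asarray(beta))))
    return X, (rng.random(n) < p).astype(float)


class TestStandardLogistic:
    def test_two_by_two_slope_is_log_odds_ratio(self):
        X, y = two_by_two(40, 10, 10, 40)
        fit = fit_logistic(X, y)
        assert fit.beta[1] == pytest.approx(math.log(16), abs=1e-4)
        assert fit.converged

    def test_null_predictor_rarely_significant(self):
        hits = 0
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(size=(500, 1))
            y = rng.integers(0, 2, 500).astype(float)
            fit = fit_logistic(X, y)
            if fit.wald_p[1] > 0.05:
                hits += 1
        assert hits >= 90

    def test_complete_separation_flagged_nonconverged(self):
        x = np.concatenate([np.linspace(0, 1, 25), np.linspace(2, 3, 25)])
        y = np.repeat([0.0, 1.0], 25)
        assert detect_complete_separation(x, y)
        fit = fit_logistic(x.reshape(-1, 1), y)
        assert not fit.converged

    def test_recovers_generating_coefficients_within_wald_band(self):
        # calibration: estimate within +-3 SE of truth in >=95% of replicates
        truth = np.array([0.8, -1.5])
        ok = 0
        for s in range(100):
            rng = np.random.default_rng(5000 + s)
            X, y = simulate_logistic(rng, 0.3, truth, 5000)
            fit = fit_logistic(X, y)
            if np.all(np.abs(fit.beta[1:] - truth) <= 3 * fit.se[1:]):
                ok += 1
        assert ok >= 95

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        y = (rng.random(100) < 0.5).astype(float)
        with pytest.raises(CollinearityError, match="b"):
            fit_logistic(X, y)

    def test_single_class_response_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(np.ones((5, 1)), np.ones(5))


class TestFirth:
    def test_finite_estimates_under_complete_separation(self):
        x = np.concatenate([np.linspace(0, 1, 25), np.linspace(2, 3, 25)])
        y = np.repeat([0.0, 1.0], 25)
        fit = fit_firth(x.reshape(-1, 1), y)
        assert fit.converged
        assert np.all(np.isfinite(fit.beta)) and np.all(np.isfinite(fit.se))
        assert fit.beta[1] > 0

    def test_penalty_vanishes_on_large_balanced_sample(self):
        rng = np.random.default_rng(11)
        X, y = simulate_logistic(rng, 0.2, [1.0], 2000)
        b_ml = fit_logistic(X, y).beta
        b_fi = fit_firth(X, y).beta
        assert b_fi[1] == pytest.approx(b_ml[1], rel=0.02)

    def test_zero_cell_matches_grid_search_of_penalized_likelihood(self):
        X, y = two_by_two(20, 10, 0, 15)  # zero (y=1, x=0) cell

        def pll(b0, b1):
            eta = b0 + b1 * X[:, 0]
            p = 1 / (1 + np.exp(-eta))
            w = p * (1 - p)
            design = np.column_stack([np.ones_like(p), X[:, 0]])
            info = design.T @ (design * w[:, None])
            ll = np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
            return ll + 0.5 * np.linalg.slogdet(info)[1]

        fit = fit_firth(X, y)
        # nested grid refinement, independent of the Newton solver
        center = np.array([0.0, 0.0])
        width = 8.0
        for _ in range(12):
            b0s = np.linspace(center[0] - width, center[0] + width, 21)
            b1s = np.linspace(center[1] - width, center[1] + width, 21)
            vals = [[pll(b0, b1) for b1 in b1s] for b0 in b0s]
            i, j = np.unravel_index(np.argmax(vals), (21, 21))
            center = np.array([b0s[i], b1s[j]])
            width *= 0.25
        assert fit.beta == pytest.approx(center, abs=1e-3)

    def test_model_p_small_for_strong_predictor(self):
        x = np.concatenate([np.linspace(0, 1, 30), np.linspace(2, 3, 30)])
        y = np.repeat([0.0, 1.0], 30)
        assert fit_firth(x.reshape(-1, 1), y).model_p < 1e-4


class TestInfluenceDiagnostics:
    def test_clean_data_has_no_outliers_usually(self):
        # mild effect size keeps fitted probabilities away from 0/1, so a
        # well-specified model should flag (almost) nothing at threshold 3
        clean = 0
        for s in range(100):
            rng = np.random.default_rng(200 + s)
            X, y = simulate_logistic(rng, 0.0, [0.5], 500)
            fit = fit_logistic(X, y)
            diag = diagnose_influence(fit, X, y, residual_threshold=3.0)
            if not diag["outlier_ids"]:
                clean += 1
        assert clean >= 95

    def test_planted_contaminant_is_detected(self):
        rng = np.random.default_rng(7)
        X, y = simulate_logistic(rng, 0.0, [2.0], 300)
        X[0] = 6.0   # extreme predictor with flipped response
        y[0] = 0.0
        fit = fit_logistic(X, y)
        diag = diagnose_influence(fit, X, y, residual_threshold=3.0,
                                  cooks_threshold=0.5)
        assert 0 in diag["outlier_ids"] or 0 in diag["influential_ids"]

    def test_thresholds_honored(self):
        rng = np.random.default_rng(8)
        X, y = simulate_logistic(rng, 0.0, [1.0], 200)
        fit = fit_logistic(X, y)
        diag = diagnose_influence(fit, X, y, residual_threshold=10.0)
        assert diag["outlier_ids"] == []

    def test_nonconverged_fit_rejected(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = np.repeat([0.0, 1.0], 10)
        fit = fit_logistic(x.reshape(-1, 1), y)
        assert not fit.converged
        with pytest.raises(ConvergenceError):
            diagnose_influence(fit, x.reshape(-1, 1), y)


class TestModelReduction:
    def test_significant_full_model_returned_unchanged(self):
        rng = np.random.default_rng(21)
        X, y = simulate_logistic(rng, 0.0, [1.5, 0.0, 0.0], 400)
        frame = pd.DataFrame(X, columns=["good", "noise1", "noise2"])
        fit = reduce_model(frame, y)
        assert fit.predictors == ["good", "noise1", "noise2"]
        assert fit.reduction_trace == []

    def test_informative_predictor_survives_reduction(self):
        rng = np.random.default_rng(22)
        n = 60
        good = rng.normal(size=n)
        y = (1 / (1 + np.exp(-2.5 * good)) > rng.random(n)).astype(float)
        frame = pd.DataFrame({"good": good})
        for j in range(5):
            noise = rng.normal(size=n)
            # noise columns engineered to separate -> standard MLE diverges
            noise[y == 1] = np.abs(noise[y == 1]) + 2 + j
            noise[y == 0] = -np.abs(noise[y == 0]) - 2 - j
            frame[f"sep{j}"] = noise
        fit = reduce_model(frame, y, method="standard")
        assert "good" in fit.predictors
        assert fit.converged and fit.model_p < 0.05

    def test_removal_order_follows_descending_wald_p(self):
        rng = np.random.default_rng(23)
        X, y = simulate_logistic(rng, 0.0, [0.0, 0.0, 0.0], 40)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        try:
            fit = reduce_model(frame, y)
        except ConvergenceError:
            return  # all-noise model may legitimately exhaust reduction
        for step in fit.reduction_trace:
            assert step["dropped"] in {"a", "b", "c"}


class TestPrediction:
    def test_zero_coefficients_give_half_probability(self):
        from tlsmeta.mcm.regression import ModelFit
        fit = ModelFit("standard", ["intercept", "x1"], np.zeros(2), np.ones(2),
                       np.ones(2), 1.0, True, 1, 0.0)
        out = predict_classes(fit, np.array([[0.0], [5.0], [-7.0]]))
        np.testing.assert_allclose(out["probabilities"], 0.5)
        assert list(out["classes"]) == [1, 1, 1]  # 0.5 >= threshold

    def test_extreme_linear_predictor_does_not_overflow(self):
        from tlsmeta.mcm.regression import ModelFit
        fit = ModelFit("standard", ["intercept", "x1"], np.array([0.0, 1000.0]),
                       np.ones(2), np.ones(2), 1.0, True, 1, 0.0)
        out = predict_classes(fit, np.array([[5.0], [-5.0]]))
        assert np.all(np.isfinite(out["probabilities"]))
        assert 0.0 <= out["probabilities"].min() <= out["probabilities"].max() <= 1.0

    def test_matches_direct_matrix_computation(self, rng):
        x = rng.normal(size=(50, 3))
        X, y = simulate_logistic(rng, 0.5, [1.0, -1.0, 0.3], 400)
        fit = fit_logistic(X, y, variable_names=["a", "b", "c"])
        out = predict_classes(fit, x)
        expected = 1 / (1 + np.exp(-(fit.beta[0] + x @ fit.beta[1:])))
        np.testing.assert_allclose(out["probabilities"], expected, atol=1e-12)

    def test_column_mismatch_rejected(self):
        from tlsmeta.mcm.regression import ModelFit
        fit = ModelFit("standard", ["intercept", "a", "b"], np.zeros(3),
                       np.ones(3), np.ones(3), 1.0, True, 1, 0.0)
        with pytest.raises(ValidationError, match="lacks columns"):
            predict_classes(fit, pd.DataFrame({"a": [1.0]}))
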