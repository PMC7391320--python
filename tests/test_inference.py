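"""Weighted regression, the cascade GLM and backward-stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from reefcascade import inference
from reefcascade.errors import DegenerateDesignError, DegenerateResponseError


def _frame(x, y, w=None, **extra):
    df = pd.DataFrame({"x": x, "z": y})
    df["weight"] = 1.0 if w is None else w
    for k, v in extra.items():
        df[k] = v
    return df


class TestWeightedRegression:
    def test_perfect_line_equal_weights(self):
        fit = inference.weighted_regression(
            _frame([1, 2, 3], [1, 2, 3]), "z ~ x", fisher_z=False
        )
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-12)
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_two_points_interpolated_exactly(self):
        fit = inference.weighted_regression(
            _frame([0, 2], [1, 5], w=[0.3, 7.0]), "z ~ x", fisher_z=False
        )
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_weighted_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            w = rng.uniform(0.1, 5.0, size=n)
            fit = inference.weighted_regression(
                _frame(x, y, w=w), "z ~ x", fisher_z=False
            )
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            assert fit.params["Intercept"] == pytest.approx(beta[0], abs=1e-10)
            assert fit.params["x"] == pytest.approx(beta[1], abs=1e-10)

    def test_unit_weights_equal_unweighted_solution(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=20), rng.normal(size=20)
        fit = inference.weighted_regression(_frame(x, y), "z ~ x", fisher_z=False)
        beta = np.polyfit(x, y, 1)
        assert fit.params["x"] == pytest.approx(beta[0], abs=1e-10)

    def test_zero_weight_points_excluded_and_counted(self):
        fit = inference.weighted_regression(
            _frame([1, 2, 3, 4], [1, 2, 3, 9], w=[1, 1, 1, 0]), "z ~ x",
            fisher_z=False,
        )
        assert fit.n_used == 3 and fit.n_excluded == 1
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficiency_raises_design_error(self):
        df = _frame([1, 2, 3, 4], [1, 2, 3, 4], x2=[2, 4, 6, 8])
        with pytest.raises(DegenerateDesignError, match="rank"):
            inference.weighted_regression(df, "z ~ x + x2", fisher_z=False)

    def test_fisher_response_back_transformed_into_unit_interval(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-40, -10, 30)
        z = 0.1 * x + rng.normal(0, 2.0, 30)  # wild z values
        fit = inference.weighted_regression(_frame(x, z), "z ~ x")
        assert fit.is_fisher_z
        for col in ("r_fit", "r_ci_low", "r_ci_high"):
            assert (fit.fitted[col].abs() <= 1.0).all()


class TestLogisticCascadeModel:
    def test_balanced_groups_give_zero_coefficients(self):
        df = pd.DataFrame({"alternating": [0, 1, 0, 1], "latitude": [0, 0, 1, 1]})
        fit = inference.logistic_cascade_model(df, "alternating ~ latitude")
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-6)
        assert fit.params["latitude"] == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_matches_logit_closed_form(self):
        # 4 successes in 24: logit(4/24) = ln(4/20)
        df = pd.DataFrame({"alternating": [1] * 4 + [0] * 20})
        fit = inference.logistic_cascade_model(df, "alternating ~ 1")
        assert fit.params["Intercept"] == pytest.approx(np.log(4 / 20), abs=1e-6)
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2)

    def test_score_equations_satisfied_at_optimum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = rng.binomial(1, p)
        df = pd.DataFrame({"alternating": y, "latitude": x})
        fit = inference.logistic_cascade_model(df, "alternating ~ latitude")
        X = np.column_stack([np.ones(80), x])
        score = X.T @ (y - fit.fitted_probabilities)
        np.testing.assert_allclose(score, 0.0, atol=1e-8)

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"alternating": [0, 0, 1, 1], "latitude": [0.0, 0.1, 1.0, 1.1]})
        with pytest.warns(UserWarning, match="separation"):
            fit = inference.logistic_cascade_model(df, "alternating ~ latitude")
        assert fit.separation_flag

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"alternating": [0, 0, 0], "latitude": [1, 2, 3]})
        with pytest.raises(DegenerateResponseError):
            inference.logistic_cascade_model(df, "alternating ~ latitude")


class TestBackwardStepwise:
    def test_all_terms_significant_is_noop(self):
        rng = np.random.default_rng(4)
        n = 150
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(2.0 * x)))
        df = pd.DataFrame({"alternating": rng.binomial(1, p), "latitude": x})
        full = inference.logistic_cascade_model(df, "alternating ~ latitude")
        final, trace = inference.backward_stepwise(full, df)
        assert final.formula == full.formula
        assert len(trace.steps) == 1

    def test_null_categorical_block_dropped(self):
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        status = rng.choice(["always_fished", "early_reserve", "late_reserve"], n)
        p = 1 / (1 + np.exp(-(1.5 * x)))
        df = pd.DataFrame(
            {"alternating": rng.binomial(1, p), "latitude": x,
             "exploitation_status": status}
        )
        full = inference.logistic_cascade_model(df)
        final, trace = inference.backward_stepwise(full, df)
        assert inference.EXPLOITATION_TERM not in final.terms
        assert "latitude" in final.terms
        assert trace.steps[0]["dropped"] == inference.EXPLOITATION_TERM

    def test_informative_covariate_survives_noise_covariates(self):
        """Majority of replicates keep the true effect, drop >= 2 noise terms."""
        rng = np.random.default_rng(8)
        kept_true, dropped_noise = 0, 0
        n_rep = 20
        for _ in range(n_rep):
            n = 200
            X = rng.normal(size=(n, 4))
            p = 1 / (1 + np.exp(-(2.0 * X[:, 0])))
            df = pd.DataFrame(X, columns=["real", "n1", "n2", "n3"])
            df["alternating"] = rng.binomial(1, p)
            full = inference.logistic_cascade_model(
                df, "alternating ~ real + n1 + n2 + n3"
            )
            final, _ = inference.backward_stepwise(full, df)
            kept_true += "real" in final.terms
            dropped_noise += sum(t not in final.terms for t in ("n1", "n2", "n3")) >= 2
        assert kept_true > n_rep / 2
        assert dropped_noise > n_rep / 2

    def test_wls_stepwise_reaches_intercept_only_under_pure_noise(self):
        rng = np.random.default_rng(10)
        df = _frame(rng.normal(size=40), rng.normal(size=40))
        full = inference.weighted_regression(df, "z ~ x", fisher_z=False)
        final, trace = inference.backward_stepwise(full, df)
        assert final.terms == []
        assert trace.steps[-1]["terms"] == "1"


def test_trend_vs_covariate_models_flat_trends_give_zero_latitude_slope():
    rng = np.random.default_rng(1)
    n = 30
    trends_df = pd.DataFrame(
        {
            "location_id": [f"L{i}" for i in range(n)],
            "trophic_group": "predators",
            "method": "ols",
            "slope": 0.42,
            "se": 0.1,
        }
    )
    meta = pd.DataFrame(
        {
            "location_id": [f"L{i}" for i in range(n)],
            "latitude": rng.uniform(-43, -14, n),
            "exploitation_status": rng.choice(
                ["always_fished", "early_reserve"], n
            ),
        }
    )
    out = inference.trend_vs_covariate_models(trends_df, meta)
    fit, _ = out["models"]["predators"]["latitude"]
    if "latitude" in fit.params.index:
        assert fit.params["latitude"] == pytest.approx(0.0, abs=1e-10)
    means = out["category_means"]
    assert np.allclose(means["mean_slope"], 0.42)
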