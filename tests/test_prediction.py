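"""OLS reporting metrics, stepwise selection and equation application."""

import numpy as np
import pandas as pd
import pytest

from feedsid import pipeline as pl
from feedsid import prediction as pred


@pytest.fixture(scope="module")
def covariates(bundle):
    return pl.composition_frame(bundle.ingredients)


@pytest.fixture(scope="module")
def sid_lys(bundle, covariates):
    return bundle.sid.loc["Lys", covariates.index].to_numpy(dtype=float)


class TestPearson:
    def test_self_correlation(self, covariates):
        r, p = pred.pearson_matrix(covariates[["NDF", "CF"]])
        assert r.loc["NDF", "NDF"] == 1.0
        assert np.allclose(r, r.T)

    def test_ndf_sid_lys(self, covariates, sid_lys):
        df = pd.DataFrame({"NDF": covariates["NDF"], "SID_Lys": sid_lys})
        r, p = pred.pearson_matrix(df)
        assert r.loc["NDF", "SID_Lys"] == pytest.approx(-0.9713, abs=5e-4)
        assert p.loc["NDF", "SID_Lys"] < 0.01

    def test_orthogonal_vectors(self):
        r, _ = pred.pearson_matrix({"x": [1, 0, 1, 0], "y": [0, 1, 1, 0]})
        assert r.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged_not_raised(self):
        r, p = pred.pearson_matrix({"x": [1, 2, 3], "flat": [5, 5, 5]})
        assert np.isnan(r.loc["x", "flat"]) and np.isnan(p.loc["x", "flat"])

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            pred.pearson_matrix({"x": [1, 2], "y": [3, 4]})


class TestOlsFit:
    def test_sid_lys_on_ndf(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys, response="SID_Lys")
        assert m.intercept == pytest.approx(100.107, abs=0.005)
        assert m.coefficients["NDF"] == pytest.approx(-1.229, abs=0.001)
        assert m.r2 == pytest.approx(0.9435, abs=5e-4)
        assert m.rsd == pytest.approx(2.88, abs=0.01)
        assert m.p_value < 0.01

    def test_sid_val_on_tgs(self, covariates, bundle):
        y = bundle.sid.loc["Val", covariates.index]
        m = pred.ols_fit(covariates[["TGS"]], y)
        assert m.coefficients["TGS"] == pytest.approx(-2.990, abs=0.005)
        assert m.r2 == pytest.approx(0.57, abs=0.005)

    def test_exact_line(self):
        x = pd.DataFrame({"x": [0.0, 1, 2, 3, 4]})
        m = pred.ols_fit(x, 2 * x["x"] + 1)
        assert m.coefficients["x"] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1.0) and m.rsd == pytest.approx(0.0, abs=1e-10)

    def test_adj_r2_below_r2(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF", "CF"]], sid_lys)
        assert m.adj_r2 <= m.r2

    def test_collinearity_error(self):
        x = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(np.linalg.LinAlgError, match="a, b"):
            pred.ols_fit(x, [1.0, 2, 3, 4, 5])

    def test_not_enough_observations(self):
        with pytest.raises(ValueError):
            pred.ols_fit(pd.DataFrame({"a": [1.0, 2]}), [1.0, 2])


class TestInvariants:
    def test_r2_equals_squared_pearson(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys)
        r, _ = pred.pearson_matrix(
            {"NDF": covariates["NDF"], "y": sid_lys})
        assert m.r2 == pytest.approx(r.loc["NDF", "y"] ** 2, abs=1e-12)

    def test_line_through_centroid(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys, response="SID_Lys")
        at_mean = m.predict({"NDF": covariates["NDF"].mean()})
        assert at_mean == pytest.approx(np.mean(sid_lys), abs=1e-9)

    def test_refit_on_own_predictions(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys)
        yhat = [m.predict({"NDF": v}) for v in covariates["NDF"]]
        m2 = pred.ols_fit(covariates[["NDF"]], yhat)
        assert m2.r2 == pytest.approx(1.0)
        assert m2.rsd == pytest.approx(0.0, abs=1e-9)


class TestStepwise:
    def test_first_entry_is_ndf_for_lysine(self, covariates, sid_lys):
        m = pred.stepwise_select(covariates[list(pl.DEFAULT_CANDIDATES)],
                                 sid_lys, response="SID_Lys")
        assert m.predictors[0] == "NDF"

    def test_single_predictor_agrees_with_ols(self, covariates, sid_lys):
        step = pred.stepwise_select(covariates[["NDF"]], sid_lys)
        ols = pred.ols_fit(covariates[["NDF"]], sid_lys)
        assert step.predictors == ols.predictors
        assert step.intercept == pytest.approx(ols.intercept, abs=1e-12)
        assert step.coefficients["NDF"] == pytest.approx(
            ols.coefficients["NDF"], abs=1e-12)

    def test_no_qualifying_candidate_gives_intercept_only(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"noise": rng.standard_normal(12)})
        y = np.ones(12) * 3.0 + 1e-6 * rng.standard_normal(12)
        m = pred.stepwise_select(x, y)
        assert m.predictors == ()
        assert m.intercept == pytest.approx(3.0, abs=1e-5)

    def test_recovers_planted_single_predictor(self):
        rng = np.random.default_rng(11)
        x = pd.DataFrame({
            "x1": rng.uniform(0, 10, 30),
            "x2": rng.uniform(0, 10, 30),
            "x3": rng.uniform(0, 10, 30),
        })
        y = 3.0 - 2.0 * x["x1"] + 0.05 * rng.standard_normal(30)
        m = pred.stepwise_select(x, y)
        assert m.predictors == ("x1",)
        assert m.coefficients["x1"] == pytest.approx(-2.0, abs=0.02)

    def test_configuration_error(self):
        with pytest.raises(ValueError, match="p_remove"):
            pred.stepwise_select(pd.DataFrame({"a": [1.0, 2, 3, 4]}),
                                 [1.0, 2, 3, 4], p_enter=0.1, p_remove=0.05)

    def test_slope_recovery_monte_carlo(self):
        """Over 200 synthetic datasets (n=10, slope -1.2, residual SD 3) the
        mean estimated slope sits within 2 Monte-Carlo SEs of the truth."""
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(200):
            x = pd.DataFrame({"x": rng.uniform(20, 50, 10)})
            y = 100.0 - 1.2 * x["x"] + rng.normal(0, 3, 10)
            slopes.append(pred.ols_fit(x, y).coefficients["x"])
        slopes = np.array(slopes)
        mc_se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - (-1.2)) < 2 * mc_se


class TestPredict:
    def test_at_fixture_mean(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys, response="SID_Lys")
        assert m.predict({"NDF": 30.188}) == pytest.approx(63.01, abs=0.05)

    def test_cp_intercept_readoff(self, covariates, bundle):
        y = bundle.sid.loc["CP", covariates.index]
        m = pred.ols_fit(covariates[["NDF"]], y, response="SID_CP")
        assert m.predict({"NDF": 0.0}) == pytest.approx(90.124, abs=0.05)

    def test_intercept_only(self):
        m = pred.RegressionModel("y", (), 7.5, {}, 0, 0, 0, float("nan"), 5)
        assert pred.predict_from_model(m, {}) == 7.5

    def test_missing_predictor(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys)
        with pytest.raises(KeyError, match="NDF"):
            pred.predict_from_model(m, {"CF": 9.0})

    def test_equation_text(self, covariates, sid_lys):
        m = pred.ols_fit(covariates[["NDF"]], sid_lys, response="SID_Lys")
        assert m.equation() == "SID_Lys = 100.107 - 1.229*NDF"


class TestEstimatorWrapper:
    def test_sklearn_protocol(self, covariates, sid_lys):
        est = pred.StepwiseLinearRegression(p_enter=0.05)
        assert est.get_params() == {"p_enter": 0.05, "p_remove": 0.10}
        est.set_params(p_remove=0.15)
        est.fit(covariates[list(pl.DEFAULT_CANDIDATES)], sid_lys)
        assert "NDF" in est.selected_
        preds = est.predict(covariates)
        assert preds.shape == (10,)
        assert est.score(covariates, sid_lys) > 0.9

    def test_composes_with_sklearn(self, covariates, sid_lys):
        from sklearn.base import clone
        est = clone(pred.StepwiseLinearRegression(p_enter=0.01))
        assert est.get_params()["p_enter"] == 0.01
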