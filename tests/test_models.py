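import itertools

import numpy as np
import pandas as pd
import pytest

from virtualforest.errors import FittingError, InvalidInputError
from virtualforest.models import (
    PredictionModel,
    boxcox_lambda,
    fit_bab_glm,
    fit_linear_best_subset,
    fit_stratified,
    loocv_rmse,
    map_predict,
    predict,
    predict_bab,
    predict_boxcox,
    predict_linear,
    predict_log,
    select_form,
)


def _metric_frame(rng, n, k=3, prefix="m"):
    return pd.DataFrame(
        {f"{prefix}{i}": rng.uniform(1.0, 10.0, n) for i in range(k)}
    )


class TestBestSubset:
    def test_noiseless_recovery(self, rng):
        X = _metric_frame(rng, 40)
        y = 2.0 + 3.0 * X["m1"].to_numpy()
        model = fit_linear_best_subset(X, y, max_vars=2)
        assert model.selected_metrics == ["m1"]
        assert model.adj_r2 == pytest.approx(1.0)
        assert model.resid_variance == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(model.coefficients, [2.0, 3.0], rtol=1e-8)

    def test_noisy_slope_within_three_se(self, rng):
        n = 50
        X = _metric_frame(rng, n)
        y = 2.0 + 3.0 * X["m0"].to_numpy() + rng.normal(0, 0.1, n)
        model = fit_linear_best_subset(X, y, max_vars=1)
        assert model.selected_metrics == ["m0"]
        se = 0.1 / np.sqrt(np.sum((X["m0"] - X["m0"].mean()) ** 2))
        assert abs(model.coefficients[1] - 3.0) < 3 * se

    def test_tie_break_by_column_order(self, rng):
        n = 30
        base = rng.uniform(1, 10, n)
        X = pd.DataFrame({"a": base, "b": base})  # identical predictors
        y = 1.0 + 2.0 * base
        model = fit_linear_best_subset(X, y, max_vars=1)
        assert model.selected_metrics == ["a"]

    def test_selected_subset_beats_all_searched_subsets(self, rng):
        """Independent oracle: adjusted R2 of every subset by direct linear
        algebra; the chosen subset must attain the maximum."""
        n, k = 35, 5
        X = _metric_frame(rng, n, k)
        y = (
            1.0
            + 2.0 * X["m0"].to_numpy()
            - 1.5 * X["m3"].to_numpy()
            + rng.normal(0, 0.5, n)
        )
        model = fit_linear_best_subset(X, y, max_vars=3)

        def adj_r2(cols):
            A = np.column_stack([np.ones(n), X[list(cols)].to_numpy()])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ beta
            ss_res = resid @ resid
            ss_tot = np.sum((y - y.mean()) ** 2)
            p = len(cols)
            return 1.0 - (ss_res / (n - p - 1)) / (ss_tot / (n - 1))

        best = max(
            adj_r2(c)
            for size in range(1, 4)
            for c in itertools.combinations(X.columns, size)
        )
        assert model.adj_r2 == pytest.approx(best, abs=1e-10)

    def test_insufficient_observations(self, rng):
        X = _metric_frame(rng, 5)
        with pytest.raises(FittingError):
            fit_linear_best_subset(X, np.ones(5), max_vars=6)

    def test_log_transform_rejects_nonpositive_column(self, rng):
        X = _metric_frame(rng, 30)
        X.loc[0, "m1"] = -1.0
        with pytest.raises(InvalidInputError, match="m1"):
            fit_linear_best_subset(X, np.ones(30) * 2, transform="log")


class TestPredictions:
    def _model(self, form="linear", coefs=(1.0, 2.0), v=0.0, lam=None):
        return PredictionModel(
            variable="BA",
            form=form,
            selected_metrics=["x"],
            coefficients=np.array(coefs),
            resid_variance=v,
            lam=lam,
        )

    def test_linear(self):
        X = pd.DataFrame({"x": [3.0]})
        assert predict_linear(self._model(), X)[0] == pytest.approx(7.0)

    def test_linear_vectorized(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        np.testing.assert_allclose(predict_linear(self._model(), X), [1, 3, 5])

    def test_missing_column_rejected(self):
        with pytest.raises(InvalidInputError):
            predict_linear(self._model(), pd.DataFrame({"z": [1.0]}))

    def test_log_no_variance_is_plain_backtransform(self):
        m = self._model(form="log", coefs=(0.0, 1.0), v=0.0)
        X = pd.DataFrame({"x": [5.0]})
        assert predict_log(m, X)[0] == pytest.approx(5.0)

    def test_log_bias_correction_beats_uncorrected(self, rng):
        """Lognormal Monte-Carlo: with y = exp(mu + eps), the corrected
        back-transform targets E[y] while the naive one targets the median."""
        n = 2000
        x = rng.uniform(1.0, 5.0, n)
        sigma = 0.6
        y = np.exp(0.5 + 1.0 * np.log(x) + rng.normal(0, sigma, n))
        X = pd.DataFrame({"x": x})
        model = fit_linear_best_subset(X, y, max_vars=1, transform="log")
        corrected = predict_log(model, X)
        naive = corrected / np.exp(model.resid_variance / 2.0)
        true_mean = np.exp(0.5 + np.log(x) + sigma**2 / 2)
        assert abs(np.mean(corrected - true_mean)) < abs(np.mean(naive - true_mean))

    def test_boxcox_lambda_one_is_identity_shift(self):
        m = self._model(form="boxcox", coefs=(1.0, 1.0), v=0.0, lam=1.0)
        X = pd.DataFrame({"x": [2.5]})
        yhat = 1.0 + 2.5
        assert predict_boxcox(m, X)[0] == pytest.approx(yhat + 1.0)

    def test_boxcox_hand_value(self):
        # lam=0.5, v=0, Yhat=2 -> (0.5*2+1)^2 = 4
        m = self._model(form="boxcox", coefs=(0.0, 1.0), v=0.0, lam=0.5)
        X = pd.DataFrame({"x": [2.0]})
        assert predict_boxcox(m, X)[0] == pytest.approx(4.0)

    def test_boxcox_limit_matches_log_backtransform(self):
        v = 1e-4  # small residual variance: corrections agree to O(v^2)
        X = pd.DataFrame({"x": [0.7]})
        m_log = self._model(form="boxcox", coefs=(0.2, 1.0), v=v, lam=0.0)
        m_lim = self._model(form="boxcox", coefs=(0.2, 1.0), v=v, lam=1e-6)
        assert predict_boxcox(m_lim, X)[0] == pytest.approx(
            predict_boxcox(m_log, X)[0], abs=1e-6
        )

    def test_boxcox_domain_violation_clamped(self):
        m = self._model(form="boxcox", coefs=(0.0, -1.0), v=0.0, lam=1.0)
        X = pd.DataFrame({"x": [5.0]})  # Yhat=-5 -> lam*Yhat+1 = -4
        with pytest.warns(UserWarning, match="clamped"):
            out = predict_boxcox(m, X)
        assert out[0] == 0.0


class TestBoxcoxLambda:
    def test_lognormal_data_lambda_near_zero(self, rng):
        y = np.exp(rng.normal(2.0, 0.5, 500))
        assert abs(boxcox_lambda(y)) < 0.3

    def test_shifted_normal_lambda_near_one(self, rng):
        # coefficient of variation ~0.3 keeps lambda identifiable
        y = np.clip(rng.normal(10.0, 3.0, 500), 0.5, None)
        assert abs(boxcox_lambda(y) - 1.0) < 0.5

    def test_constant_sample_undefined(self):
        assert np.isnan(boxcox_lambda(np.full(20, 3.0)))

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            boxcox_lambda(np.array([1.0, -1.0] * 10))


class TestBabGlm:
    def test_coefficient_recovery(self, rng):
        n = 300
        x = rng.uniform(-2, 2, n)
        eta = 0.5 + 1.5 * x
        p = 1 / (1 + np.exp(-eta))
        ba_w = rng.uniform(10, 40, n)
        bab = rng.binomial((ba_w * 10).astype(int), p) / (ba_w * 10).astype(int)
        X = pd.DataFrame({"x": x, "junk": rng.normal(size=n)})
        model = fit_bab_glm(X, bab, weights=ba_w * 10)
        assert "x" in model.selected_metrics
        i = model.selected_metrics.index("x") + 1
        # recovery within ~3 SE of a well-posed logit fit
        assert model.coefficients[i] == pytest.approx(1.5, abs=0.3)

    def test_constant_response_drops_all_metrics(self, rng):
        n = 100
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        model = fit_bab_glm(X, np.full(n, 0.5))
        assert model.selected_metrics == []

    def test_predictions_always_in_unit_interval(self, rng):
        n = 80
        X = pd.DataFrame({"a": rng.uniform(-5, 5, n)})
        bab = (X["a"] > 0).astype(float).to_numpy()  # separable
        model = fit_bab_glm(X, bab)
        wild = pd.DataFrame({"a": np.linspace(-100, 100, 50)})
        p = predict_bab(model, wild)
        assert np.all((p > 0) & (p < 1))


class TestStratifiedAndLoocv:
    def _two_strata_table(self, rng, n=80):
        x = rng.uniform(1, 10, n)
        stratum = np.where(np.arange(n) < n // 2, "s0", "s1")
        slope = np.where(stratum == "s0", 2.0, -1.0)
        y = 5.0 + slope * x + rng.normal(0, 0.1, n)
        return pd.DataFrame({"m0": x, "BA": y, "stratum": stratum})

    def test_per_stratum_slopes_recovered(self, rng):
        tbl = self._two_strata_table(rng)
        ms = fit_stratified(tbl, ["m0"], "BA", min_plots=10, max_vars=1)
        assert ms.models["s0"].coefficients[1] == pytest.approx(2.0, abs=0.05)
        assert ms.models["s1"].coefficients[1] == pytest.approx(-1.0, abs=0.05)

    def test_small_stratum_merges_into_pool(self, rng):
        tbl = self._two_strata_table(rng)
        tbl.loc[tbl.index[:3], "stratum"] = "tiny"
        ms = fit_stratified(tbl, ["m0"], "BA", min_plots=10, max_vars=1)
        assert "tiny" in ms.merged_strata
        assert ms.model_for("tiny") is ms.fallback

    def test_single_level_equals_pooled_fit(self, rng):
        tbl = self._two_strata_table(rng)
        tbl["stratum"] = "all"
        ms = fit_stratified(tbl, ["m0"], "BA", min_plots=10, max_vars=1)
        assert set(ms.models) == {"all"}

    def test_loocv_perfect_relation_rmse_zero(self, rng):
        x = rng.uniform(1, 10, 30)
        tbl = pd.DataFrame({"m0": x, "BA": 1 + 2 * x, "stratum": "all"})
        out = loocv_rmse(tbl, ["m0"], "BA", min_plots=5, max_vars=1)
        assert out == pytest.approx(0.0, abs=1e-8)

    def test_loocv_intercept_only_approaches_sd(self, rng):
        n, sigma = 200, 2.0
        y = rng.normal(10.0, sigma, n)
        tbl = pd.DataFrame({"m0": rng.normal(size=n), "BA": y, "stratum": "all"})
        out = loocv_rmse(tbl, ["m0"], "BA", min_plots=5, max_vars=1)
        assert out == pytest.approx(sigma, rel=0.15)

    def test_loocv_known_noise_level(self, rng):
        n = 300
        x = rng.uniform(5, 40, n)
        y = 3.0 + 1.2 * x + rng.normal(0, 5.0, n)
        tbl = pd.DataFrame({"m0": x, "BA": y, "stratum": "all"})
        out = loocv_rmse(tbl, ["m0"], "BA", min_plots=5, max_vars=1)
        assert 4.0 <= out <= 6.0

    def test_select_form_prefers_simpler_on_tie(self, rng):
        x = rng.uniform(1, 10, 40)
        tbl = pd.DataFrame({"m0": x, "BA": 1 + 2 * x, "stratum": "all"})
        form, scores = select_form(
            tbl, ["m0"], "BA", forms=("none", "log"), min_plots=5, max_vars=1
        )
        assert form == "none"
        assert set(scores) == {"none", "log"}


class TestMapPredict:
    def test_constant_metrics_give_constant_maps(self, rng):
        tbl = pd.DataFrame(
            {"m0": rng.uniform(1, 10, 40), "stratum": "all"}
        )
        tbl["BA"] = 2 + tbl["m0"]
        tbl["Dg"] = 20 + tbl["m0"]
        tbl["BA_b"] = 0.5
        sets = {
            v: fit_stratified(tbl, ["m0"], v, min_plots=5, max_vars=1)
            for v in ("BA", "Dg", "BA_b")
        }
        cells = pd.DataFrame({"m0": [4.0, 4.0], "stratum": "all", "forest": True})
        out = map_predict(sets, cells)
        assert out["BA"].nunique() == 1
        assert out["Dg"].iloc[0] == pytest.approx(24.0, rel=1e-6)

    def test_masked_cells_are_nodata(self, rng):
        tbl = pd.DataFrame({"m0": rng.uniform(1, 10, 30), "stratum": "all"})
        tbl["BA"] = 2 + tbl["m0"]
        tbl["Dg"] = 20 + tbl["m0"]
        tbl["BA_b"] = 0.4
        sets = {
            v: fit_stratified(tbl, ["m0"], v, min_plots=5, max_vars=1)
            for v in ("BA", "Dg", "BA_b")
        }
        cells = pd.DataFrame(
            {"m0": [4.0, 5.0], "stratum": "all", "forest": [True, False]}
        )
        out = map_predict(sets, cells)
        assert np.isnan(out.loc[1, "BA"])
        assert not np.isnan(out.loc[0, "BA"])
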