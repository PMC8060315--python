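"""OLS fitting, prediction, and parameter-recovery experiments."""

import numpy as np
import pytest

from ccsmorph import (
    CohortParams,
    DegenerateFitError,
    InclinationModel,
    InvalidInputError,
    fit_all_pairs,
    fit_ols,
    predict_ccs_angle,
    recover_parameters,
    round_half_up,
    sample_angle_table,
)
from ccsmorph.synth import generator_regression_models, printed_regression_models


def _normal_equations_oracle(x, y):
    """Brute-force closed-form OLS: solve the 2x2 normal equations."""
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    sse = float(np.sum((y - slope * x - intercept) ** 2))
    return slope, intercept, np.sqrt(sse / (n - 2))


class TestFitOls:
    def test_collinear_points(self):
        m = fit_ols([0, 1, 2], [1, 2, 3])
        assert m.slope == pytest.approx(1.0, abs=1e-12)
        assert m.intercept == pytest.approx(1.0, abs=1e-12)
        assert m.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert m.r2 == pytest.approx(1.0)

    def test_constant_response(self):
        m = fit_ols([0, 1, 2, 3], [5.5, 5.5, 5.5, 5.5])
        assert m.slope == pytest.approx(0.0, abs=1e-12)
        assert m.intercept == pytest.approx(5.5)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(100, 12, 23)
        y = 1.2 * x - 30 + rng.normal(0, 12, 23)
        m = fit_ols(x, y)
        slope, intercept, resid = _normal_equations_oracle(x, y)
        assert m.slope == pytest.approx(slope, abs=1e-10)
        assert m.intercept == pytest.approx(intercept, abs=1e-10)
        assert m.residual_sd == pytest.approx(resid, abs=1e-10)

    def test_line_passes_through_mean_point(self, rng):
        x = rng.normal(60, 13, 23)
        y = 0.7 * x + rng.normal(0, 15, 23)
        m = fit_ols(x, y)
        assert m.predict(x.mean()) == pytest.approx(y.mean(), abs=1e-10)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateFitError):
            fit_ols([2, 2, 2], [1, 2, 3])
        with pytest.raises(InvalidInputError):
            fit_ols([1, 2], [1, 2])
        with pytest.raises(InvalidInputError):
            fit_ols([1, 2, 3], [1, 2])


class TestPredict:
    # Published mean cardiac angles against published mean component
    # angles (the through-the-means identity of OLS); one decimal,
    # half-up, matching the published presentation.
    @pytest.mark.parametrize(
        "pair, x, expected",
        [
            ("alpha_sgt", 99.8, 87.8),
            ("alpha_frt", 46.8, 49.4),
            ("beta_sgt", 99.8, 34.5),
            ("beta_frt", 46.8, 147.2),
            ("beta_hzt", 61.5, 30.2),
            ("gamma", 61.5, 41.5),
        ],
    )
    def test_printed_equations_hit_printed_means(self, pair, x, expected):
        models = printed_regression_models()
        assert round_half_up(predict_ccs_angle(models[pair], x), 1) == expected

    def test_lbb_mean_within_coefficient_rounding(self):
        got = printed_regression_models()["delta"].predict(61.5)
        assert abs(got - 120.2) < 0.3

    def test_zero_slope_returns_intercept(self):
        from ccsmorph import RegressionModel

        m = RegressionModel("gamma", 0.0, 17.5, 1.0)
        assert m.predict(123.0) == 17.5

    def test_wrap_option(self):
        models = printed_regression_models()
        raw = models["alpha_hzt"].predict(61.5)
        assert raw < 0  # the printed equation yields out-of-range raw values
        assert 0 <= models["alpha_hzt"].predict(61.5, wrap=True) < 360

    def test_round_half_up(self):
        assert round_half_up(41.52, 1) == 41.5
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(2.675, 2) == 2.68


class TestFitAllPairs:
    def test_zero_noise_recovers_configured_models(self):
        p = CohortParams.default(n=23, seed=3, zero_noise=True)
        fitted = fit_all_pairs(sample_angle_table(p))
        for pair, truth in p.regression_models.items():
            assert fitted[pair].slope == pytest.approx(truth.slope, abs=1e-9)
            assert fitted[pair].intercept == pytest.approx(truth.intercept, abs=1e-9)

    def test_noisy_small_cohort_within_sampling_error(self):
        p = CohortParams.default(n=23, seed=4)
        tab = sample_angle_table(p)
        fitted = fit_all_pairs(tab)
        for pair, truth in p.regression_models.items():
            m = fitted[pair]
            x = tab[m.cardiac_column].to_numpy()
            se = m.residual_sd / (np.std(x, ddof=1) * np.sqrt(len(x) - 1))
            assert abs(m.slope - truth.slope) < 3 * se

    def test_frontal_avca_slope_is_negative(self):
        tab = sample_angle_table(CohortParams.default(n=23, seed=6))
        assert fit_all_pairs(tab)["beta_frt"].slope < 0

    def test_missing_column_is_named(self):
        tab = sample_angle_table(CohortParams.default(n=5, seed=0)).drop(columns=["gamma"])
        with pytest.raises(InvalidInputError, match="gamma"):
            fit_all_pairs(tab)


class TestInclinationModel:
    def test_fit_summary_and_predict(self):
        results = InclinationModel.from_cohort(n=23, seed=8).fit()
        assert len(results.models) == 8
        text = results.summary()
        assert "alpha_sgt" in text and "beta_frt" in text
        assert np.isfinite(results.predict("alpha_sgt", 99.8))

    def test_params_table_shape(self):
        results = InclinationModel.from_cohort(n=23, seed=8).fit()
        assert list(results.params["pair_id"]) == list(results.models)
        assert (results.params["n"] == 23).all()

    def test_plot_fits_smoke(self):
        import matplotlib

        matplotlib.use("Agg")
        results = InclinationModel.from_cohort(n=23, seed=8).fit()
        axes = results.plot_fits(pairs=["alpha_sgt", "beta_frt"])
        assert len(axes) >= 2
        import matplotlib.pyplot as plt

        plt.close("all")


class TestRecovery:
    def test_zero_noise_recovery_is_exact(self):
        p = CohortParams.default(n=23, seed=0, zero_noise=True)
        rep = recover_parameters(p, replicates=2, seed=1)
        assert np.allclose(rep.table["slope_bias"], 0.0, atol=1e-9)
        assert np.allclose(rep.table["slope_rmse"], 0.0, atol=1e-9)

    def test_rmse_bounds_bias(self):
        rep = recover_parameters(replicates=50, seed=2)
        assert (rep.table["slope_rmse"] >= rep.table["slope_bias"].abs() - 1e-12).all()

    def test_rmse_shrinks_with_cohort_size(self):
        small = recover_parameters(replicates=100, seed=3, n=23)
        large = recover_parameters(replicates=100, seed=3, n=230)
        assert (large.table["slope_rmse"] < small.table["slope_rmse"]).all()

    def test_replicates_must_be_at_least_two(self):
        from ccsmorph import InvalidParamsError

        with pytest.raises(InvalidParamsError):
            recover_parameters(replicates=1, seed=0)
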