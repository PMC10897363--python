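"""OLS fitting and the target-to-NDVI conversions."""

import numpy as np
import pytest

import _oracles
from conftest import full_mask, make_grid
from urbannature import (
    convert_esd,
    convert_qtc,
    fit_ols,
    predict_at,
    synthesize_linear_city,
)
from urbannature.regress import DegeneratePredictorError


class TestFitOls:
    def test_perfect_line(self):
        fit = fit_ols([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.n == 3

    def test_constant_response_r2_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant response"):
            fit = fit_ols([0, 1, 2], [1, 1, 1])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == 0.0

    def test_matches_normal_equations_on_random_data(self, rng):
        x = rng.uniform(-3, 5, 200)
        y = 0.7 - 1.3 * x + rng.normal(0, 0.5, 200)
        fit = fit_ols(x, y)
        a, b, r2, rmse = _oracles.normal_equation_line(x, y)
        assert fit.intercept == pytest.approx(a, abs=1e-10)
        assert fit.slope == pytest.approx(b, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)
        assert fit.rmse == pytest.approx(rmse, abs=1e-10)

    def test_rmse_uses_n_denominator(self):
        # slope = -4/20 = -0.2, intercept 0; SS_res = 3.2, so RMS over
        # n = 4 residuals is sqrt(0.8) (not the n-2 version sqrt(1.6))
        fit = fit_ols([-3, -1, 1, 3], [1, -1, 1, -1])
        assert fit.rmse == pytest.approx(np.sqrt(0.8), rel=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fit_ols([2, 2, 2], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_ols([1, 2], [1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            fit_ols([1, 2, 3], [1, 2])

    def test_r2_equals_squared_pearson_correlation(self, rng):
        x = rng.uniform(0, 1, 500)
        y = 0.1 + 0.5 * x + rng.normal(0, 0.05, 500)
        fit = fit_ols(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.r2 == pytest.approx(r**2, abs=1e-10)

    def test_least_squares_is_a_minimum(self, rng):
        x = rng.uniform(0, 1, 50)
        y = 0.3 + 0.9 * x + rng.normal(0, 0.1, 50)
        fit = fit_ols(x, y)

        def ss(a, b):
            return float(((y - a - b * x) ** 2).sum())

        best = ss(fit.intercept, fit.slope)
        for da in (-1e-3, 0, 1e-3):
            for db in (-1e-3, 0, 1e-3):
                assert ss(fit.intercept + da, fit.slope + db) >= best - 1e-12


class TestPredictAt:
    def test_linear_evaluation(self):
        fit = fit_ols([0, 1, 2], [0.3, 0.8, 1.3])  # slope 0.5, intercept 0.3
        assert predict_at(fit, 0.30) == pytest.approx(0.45)
        assert predict_at(fit, 0.0) == pytest.approx(fit.intercept)
        assert predict_at(fit, 1.0) == pytest.approx(fit.intercept + fit.slope)

    def test_out_of_ndvi_range_warns_but_reports(self):
        fit = fit_ols([0, 1, 2], [0, 1, 2])
        with pytest.warns(UserWarning, match="outside the NDVI range"):
            assert predict_at(fit, 3.0) == pytest.approx(3.0)


class TestConvertQtc:
    def test_exact_linear_relation_recovered(self):
        g = make_grid(np.linspace(0, 1, 100).reshape(10, 10), cell_size=100.0)
        v = g.with_values(0.1 + 0.5 * g.values)
        conv = convert_qtc(g, v, full_mask(g))
        assert conv.fit.r2 == pytest.approx(1.0)
        assert conv.predictions[0.30] == pytest.approx(0.25, abs=1e-12)
        assert conv.ndvi_at_40 > conv.ndvi_at_30

    def test_noisy_relation_recovered_at_large_n(self):
        g, v, mask = synthesize_linear_city(seed=5, n_cells=10_000)
        conv = convert_qtc(g, v, mask)
        assert conv.predictions[0.30] == pytest.approx(0.25, abs=0.01)

    def test_prediction_difference_equals_slope_times_gap(self):
        g, v, mask = synthesize_linear_city(seed=6, n_cells=2_000)
        conv = convert_qtc(g, v, mask)
        assert conv.predictions[0.40] - conv.predictions[0.30] == pytest.approx(
            conv.fit.slope * 0.1, abs=1e-12
        )

    def test_r2_equals_squared_correlation_of_masked_cells(self):
        g, v, mask = synthesize_linear_city(seed=7, n_cells=1_000)
        conv = convert_qtc(g, v, mask)
        from urbannature import masked_cells

        r = np.corrcoef(masked_cells(g, mask), masked_cells(v, mask))[0, 1]
        assert conv.fit.r2 == pytest.approx(r**2, abs=1e-10)

    def test_fully_green_city_is_degenerate(self):
        g = make_grid(np.ones((5, 5)), cell_size=100.0)
        v = g.with_values(np.random.default_rng(0).uniform(0.5, 0.9, (5, 5)))
        with pytest.raises(DegeneratePredictorError, match="uniformly"):
            convert_qtc(g, v, full_mask(g))

    def test_direction_flag_flips_response(self):
        g, v, mask = synthesize_linear_city(seed=8, n_cells=1_000)
        fwd = convert_qtc(g, v, mask, response="ndvi")
        rev = convert_qtc(g, v, mask, response="green_fraction")
        assert fwd.fit.r2 == pytest.approx(rev.fit.r2, abs=1e-10)
        assert fwd.fit.slope != pytest.approx(rev.fit.slope)

    def test_parameter_recovery_within_two_standard_errors(self):
        devs, ses = [], []
        for seed in range(20):
            g, v, mask = synthesize_linear_city(seed=seed, n_cells=10_000)
            conv = convert_qtc(g, v, mask)
            devs.append(abs(conv.predictions[0.30] - 0.25))
            ses.append(conv.fit.prediction_stderr(0.30))
        devs = np.array(devs)
        ses = np.array(ses)
        assert devs.mean() <= 2 * ses.mean()
        assert (devs <= 3 * ses).all()  # per-city, allow one-in-a-thousand slack


class TestConvertEsd:
    def test_identity_access_grids(self):
        vals = np.random.default_rng(1).uniform(0, 1, (10, 10))
        a = make_grid(vals, cell_size=100.0)
        conv = convert_esd(a, a, full_mask(a))
        assert conv.fit.slope == pytest.approx(1.0)
        assert conv.fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert conv.at_70 == pytest.approx(0.70)

    def test_proportional_access_grids(self):
        vals = np.random.default_rng(2).uniform(0, 1, (10, 10))
        lc = make_grid(vals, cell_size=100.0)
        nv = lc.with_values(0.9 * vals)
        conv = convert_esd(lc, nv, full_mask(lc))
        assert conv.at_70 == pytest.approx(0.63, abs=1e-10)

    def test_matches_normal_equation_oracle(self, rng):
        lc_vals = rng.uniform(0, 1, (25, 20))
        nv_vals = np.clip(0.1 + 0.8 * lc_vals + rng.normal(0, 0.1, (25, 20)), 0, 1)
        lc = make_grid(lc_vals, cell_size=100.0)
        nv = make_grid(nv_vals, cell_size=100.0)
        conv = convert_esd(lc, nv, full_mask(lc))
        a, b, r2, rmse = _oracles.normal_equation_line(
            lc_vals.ravel(), nv_vals.ravel()
        )
        assert conv.fit.intercept == pytest.approx(a, abs=1e-10)
        assert conv.fit.slope == pytest.approx(b, abs=1e-10)
        assert conv.fit.r2 == pytest.approx(r2, abs=1e-10)
        assert conv.fit.rmse == pytest.approx(rmse, abs=1e-10)
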