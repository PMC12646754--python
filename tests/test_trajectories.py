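"""Additive smooth model and trajectory feature extraction."""

import numpy as np
import pandas as pd
import pytest

from canopyage import GeneratorConfig, simulate_plot_table
from canopyage.gam import fit_additive_model
from canopyage.trajectories import (TrajectoryCurve, find_extremum, fit_trajectory,
                                    predict_curve, rainfall_contrast, rate_of_change)

GRID = np.arange(10.0, 441.0)


def table_from(age, y, name="y", rain=None, area=None):
    n = len(age)
    return pd.DataFrame({
        "stand_age_yr": age,
        "rainfall_mm_yr": rain if rain is not None else np.linspace(250, 330, n),
        "plot_area_ha": area if area is not None else np.linspace(2, 8, n),
        name: y,
    })


class TestFitAdditive:
    def test_noiseless_cover_recovery(self, truth, noiseless_table):
        """Zero-noise fit tracks the truth curve away from the steep young-age
        boundary (where no k=10 smooth can follow the curvature)."""
        fit = fit_trajectory(noiseless_table, "cover_5m_pct")
        curve = predict_curve(fit, GRID, 290.0, 4.4, allow_extrapolation=True)
        err = np.abs(curve.value - truth.cover(GRID))
        assert err[GRID >= 25].max() < 0.5
        assert err.max() < 1.5

    def test_pure_noise_r2_near_zero(self, rng):
        n = 1000
        tab = table_from(rng.uniform(1, 450, n), rng.normal(size=n))
        fit = fit_trajectory(tab, "y")
        assert abs(fit.r2_adjusted) < 0.05

    def test_exact_linear_response(self, rng):
        age = rng.uniform(1, 450, 200)
        tab = table_from(age, 2.0 + 0.09 * age)
        fit = fit_trajectory(tab, "y")
        sse = float(fit.residuals @ fit.residuals)
        sst = float(((tab["y"] - tab["y"].mean()) ** 2).sum())
        assert sse < 1e-6 * sst

    def test_log_response_requires_positive(self, rng):
        tab = table_from(rng.uniform(1, 450, 100), np.linspace(-1, 5, 100))
        with pytest.raises(ValueError, match="positive"):
            fit_trajectory(tab, "y", log_response=True)

    def test_too_few_rows(self, rng):
        tab = table_from(rng.uniform(1, 450, 10), np.ones(10))
        with pytest.raises(ValueError, match="30"):
            fit_trajectory(tab, "y")

    def test_constant_predictor_rejected(self, rng):
        tab = table_from(rng.uniform(1, 450, 100), rng.normal(size=100),
                         area=np.full(100, 4.4))
        with pytest.raises(ValueError, match="vary"):
            fit_trajectory(tab, "y")


class TestPredictCurve:
    def test_backtransform_log_fit(self, rng):
        age = np.sort(rng.uniform(1, 450, 300))
        tab = table_from(age, np.exp(2.0 + 0.003 * age))
        fit = fit_trajectory(tab, "y", log_response=True)
        grid = np.linspace(20, 430, 50)
        curve = predict_curve(fit, grid, 290.0, 4.4)
        np.testing.assert_allclose(curve.value, np.exp(2.0 + 0.003 * grid), rtol=0.01)

    def test_no_rainfall_effect_gives_identical_curves(self, truth, rng):
        # response exactly representable by the age smooth: no leakage at all
        age = rng.uniform(1, 450, 300)
        tab = table_from(age, 3.0 + 0.02 * age,
                         rain=rng.uniform(250, 330, 300),
                         area=rng.uniform(2, 8, 300))
        fit = fit_trajectory(tab, "y")
        grid = np.linspace(20, 430, 100)
        a = predict_curve(fit, grid, 302.0, 4.4)
        b = predict_curve(fit, grid, 260.0, 4.4)
        np.testing.assert_allclose(a.value, b.value, atol=1e-6)
        # curvature the k=10 basis cannot represent exactly leaks only
        # negligibly into the rainfall smooth
        flat = truth.without_rainfall_effects()
        tab2 = simulate_plot_table(flat, GeneratorConfig(n_plots=300, seed=8).zero_noise())
        fit2 = fit_trajectory(tab2, "basal_area_m2ha")
        a2 = predict_curve(fit2, grid, 302.0, 4.4)
        b2 = predict_curve(fit2, grid, 260.0, 4.4)
        np.testing.assert_allclose(a2.value, b2.value, atol=0.05)

    def test_extrapolation_guard(self, default_table):
        fit = fit_trajectory(default_table, "h_max_m")
        with pytest.raises(ValueError, match="outside fitted"):
            predict_curve(fit, np.array([0.1, 100.0]), 290.0, 4.4)
        curve = predict_curve(fit, np.array([0.1, 100.0]), 290.0, 4.4,
                              allow_extrapolation=True)
        assert np.all(np.isfinite(curve.value))


class TestRates:
    def test_linear_curve_constant_decadal_rate(self):
        grid = np.arange(0.0, 101.0)
        c = TrajectoryCurve(grid, 0.09 * grid, 290.0, 4.4, "y")
        np.testing.assert_allclose(rate_of_change(c), 0.9, rtol=1e-9)

    def test_constant_curve_zero_rate(self):
        grid = np.arange(0.0, 101.0)
        c = TrajectoryCurve(grid, np.full_like(grid, 7.0), 290.0, 4.4, "y")
        np.testing.assert_allclose(rate_of_change(c), 0.0, atol=1e-12)

    def test_quadratic_derivative(self):
        grid = np.arange(0.0, 21.0)
        c = TrajectoryCurve(grid, grid ** 2, 290.0, 4.4, "y")
        # dy/dt at t=10 is 20/yr → 200/decade (central differences are exact
        # for quadratics up to O(step²))
        assert rate_of_change(c)[10] == pytest.approx(200.0, rel=1e-9)

    def test_coarse_grid_rejected(self):
        grid = np.arange(0.0, 101.0, 10.0)
        c = TrajectoryCurve(grid, grid, 290.0, 4.4, "y")
        with pytest.raises(ValueError, match="coarse"):
            rate_of_change(c)

    def test_integral_of_rate_reconstructs_curve(self, default_table):
        fit = fit_trajectory(default_table, "cover_5m_pct")
        grid = np.arange(10.0, 441.0)
        curve = predict_curve(fit, grid, 290.0, 4.4, allow_extrapolation=True)
        rate = rate_of_change(curve) / 10.0
        rebuilt = curve.value[0] + np.concatenate(
            [[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0)])
        np.testing.assert_allclose(rebuilt, curve.value, atol=0.05)


class TestExtrema:
    def test_truth_cover_peak_recovered(self, truth):
        grid = np.arange(1.0, 451.0, 0.5)
        c = TrajectoryCurve(grid, truth.cover(grid), 290.0, 4.4, "cover")
        pk = find_extremum(c, "maximum")
        assert pk.peak_age == pytest.approx(120.0, abs=1.0)
        assert pk.peak_value == pytest.approx(48.0, abs=0.1)
        assert not pk.at_boundary

    def test_monotone_curve_boundary_flag(self):
        grid = np.arange(0.0, 101.0)
        c = TrajectoryCurve(grid, np.log1p(grid), 290.0, 4.4, "y")
        assert find_extremum(c, "maximum").at_boundary

    def test_parabola_refined_exactly(self):
        grid = np.arange(0.0, 201.0, 2.0)  # vertex at 100 lies on the grid midline
        c = TrajectoryCurve(grid, -(grid - 100.0) ** 2, 290.0, 4.4, "y")
        pk = find_extremum(c, "maximum")
        assert pk.peak_age == pytest.approx(100.0, abs=1e-9)

    def test_minimum_of_hcv_truth(self, truth):
        grid = np.arange(1.0, 451.0, 0.5)
        c = TrajectoryCurve(grid, truth.h_cv(grid), 290.0, 4.4, "h_cv")
        tr = find_extremum(c, "minimum")
        assert tr.kind == "minimum"
        assert tr.peak_age == pytest.approx(75.0, abs=1.0)

    def test_mean_rates_bracket_peak(self, truth):
        grid = np.arange(1.0, 451.0)
        c = TrajectoryCurve(grid, truth.cover(grid), 290.0, 4.4, "cover")
        pk = find_extremum(c, "maximum")
        assert pk.mean_rate_before > 0 > pk.mean_rate_after
        # mean decline rate from the 48% peak to 20% at 450 ≈ 0.85 pp/decade
        assert -pk.mean_rate_after == pytest.approx(28.0 / 33.0, abs=0.02)


class TestRainfallContrast:
    def test_sign_and_magnitude_on_default_data(self, default_table):
        fit = fit_trajectory(default_table, "h_max_m")
        grid = np.arange(10.0, 441.0)
        _, at_peak = rainfall_contrast(fit, grid)
        assert at_peak == pytest.approx(1.2, abs=0.5)
        fit_hcv = fit_trajectory(default_table, "h_cv")
        diff, _ = rainfall_contrast(fit_hcv, grid)
        assert diff.mean() < 0  # drier stands are more heterogeneous

    def test_out_of_range_rainfall_rejected(self, default_table):
        fit = fit_trajectory(default_table, "h_max_m")
        with pytest.raises(ValueError, match="rainfall"):
            rainfall_contrast(fit, np.arange(10.0, 441.0), r_lo=100.0)


class TestAdjustedR2:
    def test_hand_computed_example(self):
        # small worked example with a fixed smoothing parameter
        rng = np.random.default_rng(0)
        age = np.linspace(1, 450, 40)
        y = 5.0 + 0.01 * age + rng.normal(0, 0.5, 40)
        data = {"stand_age_yr": age, "y": y}
        fit = fit_additive_model(data, "y", ["stand_age_yr"], lambdas=np.array([10.0]))
        sse = float(fit.residuals @ fit.residuals)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1 - sse / sst
        n, edf = 40, fit.edf
        expected = 1 - (1 - r2) * (n - 1) / (n - edf - 1)
        assert fit.r2_adjusted == pytest.approx(expected, rel=1e-12)
        assert fit.r2_adjusted <= 1.0

    def test_noiseless_saturated_fit_near_one(self, noiseless_table):
        fit = fit_trajectory(noiseless_table, "h_max_m")
        assert fit.r2_adjusted > 0.99

    def test_smoother_consistency_noise_ladder(self, truth):
        """Sup-norm error decreases as generator noise shrinks to zero."""
        errs = []
        for scale in [1.0, 0.5, 0.0]:
            cfg = GeneratorConfig(n_plots=400, seed=17)
            cfg = GeneratorConfig(n_plots=400, seed=17, noise_sd={
                k: v * scale for k, v in cfg.noise_sd.items()})
            tab = simulate_plot_table(truth, cfg)
            fit = fit_trajectory(tab, "h_max_m")
            grid = np.arange(30.0, 441.0)
            curve = predict_curve(fit, grid, 290.0, 4.4, allow_extrapolation=True)
            errs.append(np.abs(curve.value - truth.h_max(grid)).max())
        assert errs[2] < errs[1] < errs[0]


class TestMgcvCrossCheck:
    def test_matches_mgcv_reml_fit(self, tmp_path, rng):
        """Independent oracle: mgcv's REML fit of the same smooth signal.

        Both smoothers should track sin(x) fitted from noisy data to within
        the noise floor; they are compared to the known signal, not tuned to
        each other.
        """
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        n = 150
        x = np.sort(rng.uniform(0, 2 * np.pi, n))
        y = np.sin(x) + rng.normal(0, 0.1, n)
        pd.DataFrame({"x": x, "y": y}).to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'library(mgcv)\nd <- read.csv("%s")\n'
            'm <- gam(y ~ s(x, k=10), data=d, method="REML")\n'
            'g <- seq(0.1, 2*pi - 0.1, length.out=50)\n'
            'write.csv(data.frame(x=g, fit=predict(m, data.frame(x=g))), "%s", row.names=FALSE)\n'
            % (tmp_path / "d.csv", tmp_path / "out.csv"))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        fit = fit_additive_model({"x": x, "y": y}, "y", ["x"])
        mine = fit.predict({"x": ref["x"].to_numpy()})
        sig = np.sin(ref["x"].to_numpy())
        assert np.sqrt(np.mean((mine - sig) ** 2)) < 0.08
        assert np.sqrt(np.mean((ref["fit"].to_numpy() - sig) ** 2)) < 0.08
        assert np.sqrt(np.mean((mine - ref["fit"].to_numpy()) ** 2)) < 0.1
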