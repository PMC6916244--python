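"""Cumulative curves, derivative endpoint rule, rescaling, ψ mapping, VC values."""

import numpy as np
import pytest

from xylemae.vc import (
    CumulativeCurve,
    StressStrainModel,
    VulnerabilityCurve,
    compare_curves,
    cumulate,
    end_percentage,
    find_endpoint,
    fit_stress_strain,
    map_time_to_psi,
    moving_derivative,
    relative_difference_percent,
    rescale_percentage,
    vulnerability_values,
)


class TestCumulate:
    def test_unit_events_step_to_their_total(self):
        curve = cumulate([1800.0, 1800.0, 1800.0], bin_minutes=10, span=(0, 3600))
        assert curve.values[0] == 0.0
        assert curve.values[-1] == pytest.approx(3.0)
        assert np.all(np.diff(curve.values) >= 0)

    def test_probability_weights_accumulate(self):
        curve = cumulate([100.0, 200.0], weights=[0.2, 0.3], bin_minutes=10, span=(0, 1200))
        assert curve.final == pytest.approx(0.5)

    def test_matches_fine_grid_prefix_sum_oracle(self, rng):
        times = np.sort(rng.uniform(0, 7200, 300))
        weights = rng.uniform(0, 1, 300)
        curve = cumulate(times, weights=weights, bin_minutes=10, span=(0, 7200))
        # oracle: average the exact step function over each bin on a 10-ms grid
        grid = np.arange(0, 7200, 0.01)
        steps = np.cumsum(weights)[np.searchsorted(times, grid, side="right") - 1]
        steps[grid < times[0]] = 0.0
        oracle = steps.reshape(12, -1).mean(axis=1)
        np.testing.assert_allclose(curve.values, oracle, atol=1e-3)

    def test_empty_input_yields_zero_curve(self):
        curve = cumulate([], bin_minutes=10, span=(0, 3600))
        assert curve.final == 0.0
        assert len(curve.values) == 6


class TestDerivatives:
    def _cubic(self, a=1e-9, n=200):
        t = np.arange(n) * 600.0
        return CumulativeCurve(bin_centers=t, values=a * t**3, bin_seconds=600.0)

    def test_third_derivative_of_cubic_is_6a(self):
        a = 1e-9
        d3 = moving_derivative(self._cubic(a), 3, 120.0)
        np.testing.assert_allclose(d3.values[30:-30], 6 * a, rtol=0.02)

    def test_linear_curve_has_constant_slope_and_zero_third(self):
        t = np.arange(200) * 600.0
        curve = CumulativeCurve(bin_centers=t, values=0.05 * t, bin_seconds=600.0)
        d1 = moving_derivative(curve, 1, 60.0)
        d3 = moving_derivative(curve, 3, 60.0)
        np.testing.assert_allclose(d1.values, 0.05, rtol=1e-9)
        np.testing.assert_allclose(d3.values, 0.0, atol=1e-12)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            moving_derivative(self._cubic(n=10), 1, 48 * 60.0)

    def test_matches_spline_oracle_on_noisy_sigmoid(self, rng):
        from scipy.interpolate import make_smoothing_spline

        t = np.arange(300) * 600.0
        clean = 500 / (1 + np.exp(-(t - 90000) / 15000))
        noisy = clean + rng.normal(0, 0.5, len(t))
        d1 = moving_derivative(
            CumulativeCurve(bin_centers=t, values=np.maximum.accumulate(noisy), bin_seconds=600.0),
            1,
            100.0,
        )
        spline = make_smoothing_spline(t, noisy)
        oracle = spline.derivative()(t)
        mid = slice(20, -20)
        scale = np.max(np.abs(oracle[mid]))
        # both routes estimate the same derivative from the same noisy series;
        # pointwise they differ by the oracle's own noise wiggle, so compare
        # in RMS, and check the moving-window slope against the true derivative
        rms = np.sqrt(np.mean((d1.values[mid] - oracle[mid]) ** 2))
        assert rms < 0.2 * scale
        true_d1 = np.gradient(clean, t)
        assert np.max(np.abs(d1.values[mid] - true_d1[mid])) < 0.1 * np.max(true_d1)


class TestEndpoint:
    def _logistic(self, n=432, mid=130000.0, scale=20000.0):
        t = np.arange(n) * 600.0
        return t, 1000 / (1 + np.exp(-(t - mid) / scale))

    def test_saturating_sigmoid_matches_numeric_oracle_within_one_bin(self):
        t, cum = self._logistic()
        curve = CumulativeCurve(bin_centers=t, values=cum, bin_seconds=600.0)
        found = find_endpoint(curve, d1_window_minutes=30, d3_window_minutes=30)
        d1 = np.gradient(cum, t)
        d3 = np.gradient(np.gradient(d1, t), t)
        i1 = int(np.argmax(d1))
        oracle = None
        for i in range(i1 + 1, len(t) - 1):
            if d3[i] >= d3[i - 1] and d3[i] > d3[i + 1]:
                oracle = t[i]
                break
        assert found is not None
        assert abs(found - oracle) <= 600.0

    def test_strictly_accelerating_curve_has_no_endpoint(self):
        t = np.arange(300) * 600.0
        curve = CumulativeCurve(bin_centers=t, values=(t / t[-1]) ** 3 * 100, bin_seconds=600.0)
        assert find_endpoint(curve, 30, 30) is None

    def test_endpoint_precedes_a_flat_tail(self):
        t, cum = self._logistic(n=300, mid=60000.0, scale=8000.0)
        cum[200:] = cum[200]  # saturated: AE stops entirely
        curve = CumulativeCurve(bin_centers=t, values=cum, bin_seconds=600.0)
        found = find_endpoint(curve, 30, 30)
        assert found is not None
        assert found < t[200]


class TestRescaling:
    def test_reported_end_percentages(self):
        assert end_percentage(541, 518, 1100) == (pytest.approx(96.2727, abs=1e-3), 96)
        assert end_percentage(541, 457, 1100) == (pytest.approx(90.7272, abs=1e-3), 91)
        assert end_percentage(0, 500, 500)[1] == 100

    def test_curve_runs_zero_to_end_percent(self):
        curve = cumulate(np.linspace(0, 7000, 457), bin_minutes=10, span=(0, 7200))
        percent, end = rescale_percentage(curve, 541, 457, 1100)
        assert percent[0] < percent[-1] == pytest.approx(end)
        assert end == pytest.approx(90.7272, abs=1e-3)

    def test_start_at_native_alternative_convention(self):
        # first bins empty: the curve should sit exactly at the native floor there
        curve = cumulate(np.linspace(3000, 7000, 100), bin_minutes=10, span=(0, 7200))
        percent, end = rescale_percentage(curve, 541, 457, 1100, start_at_native=True)
        assert percent[-1] == pytest.approx(end)
        assert percent[0] == pytest.approx(100 * 541 / 1100)

    def test_zero_total_vessels_rejected(self):
        curve = cumulate([10.0], span=(0, 1200))
        with pytest.raises(ValueError, match="positive"):
            rescale_percentage(curve, 0, 1, 0)

    def test_overfull_rescale_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            end_percentage(900, 300, 1100)


class TestStressStrain:
    planted = StressStrainModel(breakpoints=(0.5, 1.2), intercept=-0.2, slopes=(-2.0, -1.5, -5.0))

    def test_noise_free_recovery_to_grid_resolution(self):
        s = np.linspace(0, 2, 41)  # breakpoints 0.5 and 1.2 are sample quantiles
        fit = fit_stress_strain(s, self.planted.psi(s), n_grid=37)
        assert fit.breakpoints[0] == pytest.approx(0.5, abs=1e-9)
        assert fit.breakpoints[1] == pytest.approx(1.2, abs=1e-9)
        np.testing.assert_allclose(fit.slopes, self.planted.slopes, atol=1e-9)
        np.testing.assert_allclose(fit.psi(s), self.planted.psi(s), atol=1e-9)

    def test_perfectly_linear_data_accepted_with_equal_slopes(self):
        s = np.linspace(0, 2, 30)
        fit = fit_stress_strain(s, -0.1 - 1.7 * s)
        np.testing.assert_allclose(fit.slopes, -1.7, atol=1e-8)
        np.testing.assert_allclose(fit.psi(s), -0.1 - 1.7 * s, atol=1e-8)

    def test_noisy_slopes_unbiased_within_three_sd(self, rng):
        # design where the planted breakpoints lie on the candidate quantile
        # grid, so the grid search adds no discretization bias
        ests = []
        s = np.linspace(0, 2, 41)
        for _ in range(30):
            psi = self.planted.psi(s) + rng.normal(0, 0.05, len(s))
            ests.append(fit_stress_strain(s, psi, n_grid=37).slopes)
        ests = np.array(ests)
        for k in range(3):
            spread = ests[:, k].std(ddof=1)
            assert abs(ests[:, k].mean() - self.planted.slopes[k]) < 3 * spread / np.sqrt(30) + 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_stress_strain([0.0, 1.0, 2.0], [0.0, -1.0, -2.0])

    def test_mapping_continuous_at_breakpoints(self):
        b1, b2 = self.planted.breakpoints
        eps = 1e-12
        assert self.planted.psi(b1 - eps) == pytest.approx(self.planted.psi(b1 + eps), abs=1e-9)
        assert self.planted.psi(b2 - eps) == pytest.approx(self.planted.psi(b2 + eps), abs=1e-9)

    def test_generator_round_trip_is_exact(self, small_experiment):
        exp = small_experiment
        cfg = exp.config
        psi = map_time_to_psi(cfg.strain_model, exp.strain_trace["strain"].to_numpy())
        np.testing.assert_allclose(psi, cfg.psi_of_time(exp.strain_trace["time_s"].to_numpy()))

    def test_extrapolation_warns(self):
        model = StressStrainModel(
            breakpoints=(0.5, 1.2), intercept=-0.2, slopes=(-2, -1.5, -5), strain_range=(0.0, 2.0)
        )
        with pytest.warns(UserWarning, match="extrapolat"):
            map_time_to_psi(model, np.array([2.5]))


class TestVulnerabilityValues:
    def _logistic_curve(self, mid=-2.3, end=100.0, scale=0.4):
        psi = np.linspace(-0.1, -6.0, 400)
        percent = end / (1 + np.exp((psi - mid) / scale))
        return VulnerabilityCurve(psi=psi, percent=percent, end_percent=end)

    def test_logistic_midpoint_recovered(self):
        vals = vulnerability_values(self._logistic_curve(mid=-2.3))
        assert vals.v50 == pytest.approx(-2.30, abs=0.02)
        assert vals.v12 >= vals.v50 >= vals.v88

    def test_step_curve_collapses_all_levels(self):
        psi = np.linspace(-0.1, -6.0, 1200)
        percent = np.where(psi <= -3.0, 90.0, 0.0)
        vc = VulnerabilityCurve(psi=psi, percent=percent, end_percent=90.0)
        vals = vulnerability_values(vc)
        for v in (vals.v12, vals.v50, vals.v88):
            assert v == pytest.approx(-3.0, abs=0.05)

    def test_level_above_ceiling_is_undefined(self):
        vals = vulnerability_values(self._logistic_curve(end=90.7))
        assert vals.v100 is None
        assert vals.v88 is not None

    def test_noisy_curve_matches_noiseless_crossings(self, rng):
        clean = self._logistic_curve()
        noisy = VulnerabilityCurve(
            psi=clean.psi,
            percent=np.clip(clean.percent + rng.normal(0, 1.0, len(clean.psi)), 0, None),
            end_percent=clean.end_percent,
        )
        v_clean = vulnerability_values(clean)
        v_noisy = vulnerability_values(noisy)
        for level in (12.0, 50.0, 88.0):
            assert v_noisy.levels[level] == pytest.approx(v_clean.levels[level], abs=0.05)


class TestCompareCurves:
    def _curve(self, offset=0.0):
        psi = np.linspace(-0.1, -6.0, 300)
        percent = np.clip(91 / (1 + np.exp((psi + 2.34) / 0.4)) + offset, 0, None)
        return VulnerabilityCurve(psi=psi, percent=percent, end_percent=91.0 + offset)

    def test_identical_curves_differ_nowhere(self):
        out = compare_curves(self._curve(), self._curve())
        assert out["max_abs_difference"] == pytest.approx(0.0, abs=1e-12)
        assert out["v50_relative_difference_percent"] == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset_is_reported_exactly(self):
        out = compare_curves(self._curve(offset=5.0), self._curve())
        assert out["mean_abs_difference"] == pytest.approx(5.0, abs=0.05)

    def test_reported_v50_relative_difference(self):
        exact, reported = relative_difference_percent(-2.30, -2.34)
        assert exact == pytest.approx(100 * 0.04 / 2.34, abs=1e-9)
        assert reported == 2

    def test_disjoint_ranges_rejected(self):
        a = VulnerabilityCurve(psi=np.linspace(-1, -2, 10), percent=np.linspace(0, 50, 10), end_percent=50)
        b = VulnerabilityCurve(psi=np.linspace(-3, -4, 10), percent=np.linspace(0, 50, 10), end_percent=50)
        with pytest.raises(ValueError, match="overlap"):
            compare_curves(a, b)
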