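"""Forward-model oracles: kinetics step response, calibration curves,
AR noise statistics and the composed CGM simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmerr.error_model import (
    ARNoiseParams,
    CalibrationModelSpec,
    CalibrationParams,
    GlucoseTrace,
    KineticsParams,
    SensorErrorParams,
    apply_calibration,
    bg_to_ig,
    eval_calibration,
    simulate_ar_noise,
    simulate_cgm,
)
from conftest import constant_trace


class TestGlucoseTrace:
    @pytest.mark.parametrize(
        "times, values",
        [
            ([0, 1, 1], [100, 100, 100]),  # non-increasing
            ([0, 1, 2], [100, -5, 100]),  # non-positive
            ([0, 1, 2], [100, np.nan, 100]),  # non-finite
        ],
    )
    def test_invalid_traces_rejected(self, times, values):
        with pytest.raises(ValueError):
            GlucoseTrace(np.array(times, float), np.array(values, float))

    def test_segments_iterate_contiguous_runs(self):
        tr = GlucoseTrace(np.arange(6.0), np.full(6, 100.0), [0, 0, 1, 1, 1, 2])
        lengths = [sl.stop - sl.start for sl in tr.iter_segments()]
        assert lengths == [2, 3, 1]


class TestKinetics:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        tau=st.floats(0.0, 60.0),
        level=st.floats(50.0, 350.0),
    )
    def test_unit_gain_on_constant_input(self, tau, level):
        """h(t) integrates to one: constant BG passes through unchanged."""
        ig = bg_to_ig(constant_trace(level), KineticsParams(tau))
        np.testing.assert_allclose(ig.values, level, rtol=1e-12)

    def test_tau_zero_is_identity(self):
        rng = np.random.default_rng(1)
        bg = GlucoseTrace(np.arange(100.0), 100 + 50 * rng.random(100))
        ig = bg_to_ig(bg, KineticsParams(0.0))
        np.testing.assert_array_equal(ig.values, bg.values)

    def test_step_response_matches_closed_form(self):
        """Exact ZOH discretization reproduces the analytic first-order
        step response 180 - 80*exp(-(t-t0)/tau) at the grid points."""
        t = np.arange(0.0, 200.0)
        t0, tau = 50.0, 10.0
        bg = GlucoseTrace(t, np.where(t <= t0, 100.0, 180.0))
        ig = bg_to_ig(bg, KineticsParams(tau))
        after = t > t0
        expected = 180.0 - 80.0 * np.exp(-(t[after] - t0) / tau)
        assert np.max(np.abs(ig.values[after] - expected)) <= 0.5

    def test_monotone_delay_on_ramp(self):
        t = np.arange(0.0, 120.0)
        bg = GlucoseTrace(t, 100.0 + t)
        ig = bg_to_ig(bg, KineticsParams(8.0))
        assert np.all(ig.values[1:] < bg.values[1:])

    def test_grid_refinement_consistency(self):
        """1-min and 0.1-min discretizations agree for a smooth profile."""
        tau = 10.0
        f = lambda t: 130.0 + 20.0 * np.sin(2 * np.pi * t / 720.0)
        t1 = np.arange(0.0, 720.0, 1.0)
        t01 = np.arange(0.0, 720.0, 0.1)
        ig1 = bg_to_ig(GlucoseTrace(t1, f(t1)), KineticsParams(tau))
        ig01 = bg_to_ig(GlucoseTrace(t01, f(t01)), KineticsParams(tau))
        common = np.isin(np.round(t01, 6), np.round(t1, 6))
        assert np.max(np.abs(ig01.values[common] - ig1.values)) <= 0.1

    def test_nonuniform_segment_rejected(self):
        bg = GlucoseTrace(np.array([0.0, 1.0, 3.0]), np.full(3, 100.0))
        with pytest.raises(ValueError, match="uniform"):
            bg_to_ig(bg, KineticsParams(5.0))

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            KineticsParams(-1.0)


class TestCalibration:
    def test_constant_gain(self):
        spec = CalibrationModelSpec("poly0", "poly0")
        a, b = eval_calibration(
            spec, CalibrationParams((0.95,), (7.3,)), [0.0, 5000.0, 14000.0]
        )
        np.testing.assert_allclose(a, 0.95)
        np.testing.assert_allclose(b, 7.3)

    def test_poly2_identity_gain(self):
        spec = CalibrationModelSpec("poly2", "poly0")
        a, _ = eval_calibration(
            spec, CalibrationParams((1.0, 0.0, 0.0), (0.0,)), np.arange(0, 14400, 60)
        )
        np.testing.assert_allclose(a, 1.0)

    def test_exponential_form(self):
        """exp family is p1 + (p0 - p1) * exp(-t_days / p2)."""
        spec = CalibrationModelSpec("exp", "poly0")
        a, _ = eval_calibration(
            spec, CalibrationParams((1.2, 0.8, 2.0), (0.0,)), [2.0 * 1440.0]
        )
        np.testing.assert_allclose(a, 0.8 + 0.4 * np.exp(-1.0), rtol=1e-12)

    def test_coefficient_count_mismatch_rejected(self):
        spec = CalibrationModelSpec("poly2", "poly0")
        with pytest.raises(ValueError, match="coefficient"):
            eval_calibration(spec, CalibrationParams((1.0, 0.0), (0.0,)), [0.0])

    def test_negative_time_rejected(self):
        spec = CalibrationModelSpec("poly0", "poly0")
        with pytest.raises(ValueError):
            eval_calibration(spec, CalibrationParams((1.0,), (0.0,)), [-1.0])

    def test_apply_identity(self):
        ig = constant_trace(123.0)
        out = apply_calibration(
            ig, CalibrationModelSpec("poly0", "poly0"), CalibrationParams((1.0,), (0.0,))
        )
        np.testing.assert_array_equal(out.values, ig.values)

    def test_apply_population_median_gain_offset(self):
        out = apply_calibration(
            constant_trace(100.0),
            CalibrationModelSpec("poly0", "poly0"),
            CalibrationParams((0.95,), (7.3,)),
        )
        np.testing.assert_allclose(out.values, 102.3)

    def test_apply_time_varying_gain(self):
        t5d = 5.0 * 1440.0
        tr = GlucoseTrace(np.array([t5d]), np.array([100.0]))
        out = apply_calibration(
            tr,
            CalibrationModelSpec("poly1", "poly0"),
            CalibrationParams((1.0, 0.01), (3.0,)),
        )
        np.testing.assert_allclose(out.values, 105.0 + 3.0, rtol=1e-12)


class TestARNoise:
    def test_white_noise_sample_sd(self):
        noise = ARNoiseParams(np.empty(0), 1.0)
        v = simulate_ar_noise(noise, 200_000, seed=0)
        assert abs(np.std(v) - 1.0) < 0.02

    def test_ar1_stationary_variance(self):
        """Yule-Walker closed form: var = sigma^2 / (1 - alpha1^2)."""
        noise = ARNoiseParams(np.array([0.5]), 1.0)
        v = simulate_ar_noise(noise, 200_000, seed=1)
        assert abs(np.var(v) - 1.0 / 0.75) < 0.02 * (1.0 / 0.75)

    def test_ar2_lag1_autocorrelation(self):
        """Yule-Walker: rho(1) = alpha1 / (1 - alpha2)."""
        noise = ARNoiseParams(np.array([1.30, -0.42]), 3.19)
        v = simulate_ar_noise(noise, 200_000, seed=2)
        rho1 = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert abs(rho1 - 1.30 / 1.42) < 0.02

    @pytest.mark.parametrize("alpha", [[1.5], [0.5, 0.6], [1.0, 0.0], [2.0, -1.0]])
    def test_stationarity_gate(self, alpha):
        with pytest.raises(ValueError, match="stationar"):
            ARNoiseParams(np.array(alpha, float), 1.0)

    def test_seed_reproducibility(self):
        noise = ARNoiseParams(np.array([1.30, -0.42]), 3.19)
        np.testing.assert_array_equal(
            simulate_ar_noise(noise, 100, seed=7), simulate_ar_noise(noise, 100, seed=7)
        )


def _ar2_stationary_sd(alpha1, alpha2, sigma):
    return sigma * np.sqrt(
        (1 - alpha2) / ((1 + alpha2) * ((1 - alpha2) ** 2 - alpha1**2))
    )


class TestSimulateCgm:
    def test_all_error_sources_off(self):
        bg = constant_trace(150.0, n=600)
        params = SensorErrorParams(
            KineticsParams(0.0),
            CalibrationModelSpec("poly0", "poly0"),
            CalibrationParams((1.0,), (0.0,)),
            ARNoiseParams(np.empty(0), 0.0),
        )
        cgm = simulate_cgm(bg, params, cgm_period=5.0, seed=0)
        np.testing.assert_array_equal(cgm.values, 150.0)
        np.testing.assert_array_equal(cgm.times, bg.times[::5])

    def test_steady_state_gain_offset(self):
        bg = constant_trace(200.0, n=600)
        params = SensorErrorParams(
            KineticsParams(10.0),
            CalibrationModelSpec("poly0", "poly0"),
            CalibrationParams((0.9,), (10.0,)),
            ARNoiseParams(np.empty(0), 0.0),
        )
        cgm = simulate_cgm(bg, params, cgm_period=5.0, seed=0)
        after = cgm.times > 100.0
        np.testing.assert_allclose(cgm.values[after], 190.0, atol=1e-6)

    def test_noise_sd_matches_ar2_stationary_formula(self, median_params):
        from cgmerr.synthetic_data import generate_bg

        bg = generate_bg(10.0, seed=3)
        noisy = simulate_cgm(bg, median_params, seed=4)
        from dataclasses import replace

        quiet = simulate_cgm(
            bg, replace(median_params, noise=ARNoiseParams(np.empty(0), 0.0)), seed=4
        )
        resid = noisy.values - quiet.values
        ok = ~(noisy.saturated | quiet.saturated)
        expected = _ar2_stationary_sd(1.30, -0.42, 3.19)
        assert abs(np.std(resid[ok]) - expected) / expected < 0.15

    def test_clipping_flags_saturated_samples(self):
        bg = constant_trace(340.0, n=600)
        params = SensorErrorParams(
            KineticsParams(0.0),
            CalibrationModelSpec("poly0", "poly0"),
            CalibrationParams((1.3,), (0.0,)),  # 442 -> clipped to 400
            ARNoiseParams(np.empty(0), 0.0),
        )
        cgm = simulate_cgm(bg, params, seed=0)
        assert np.all(cgm.saturated)
        np.testing.assert_array_equal(cgm.values, 400.0)
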