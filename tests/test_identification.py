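"""Identification machinery: prediction, step-1 NLS, AR fitting,
whitening, BIC and the two-step / single-step procedures."""

import math
from dataclasses import replace

import numpy as np
import pytest

from cgmerr.error_model import (
    ARNoiseParams,
    CalibrationModelSpec,
    CalibrationParams,
    KineticsParams,
    SensorErrorParams,
    simulate_ar_noise,
)
from cgmerr.identification import (
    FitResult,
    compare_fits,
    compute_bic,
    fit_ar,
    fit_step1,
    params_to_dict,
    predict_igs,
    select_ar_order,
    single_step_identify,
    two_step_identify,
    whiten_residuals,
)
from cgmerr.recovery import true_reference_pairs
from cgmerr.smoothing import MatchedPairs, SmoothProfile, match_cgm
from cgmerr.synthetic_data import CohortSpec, StudyDesign, generate_cohort

POLY2_POLY0 = CalibrationModelSpec("poly2", "poly0")
POLY0_POLY0 = CalibrationModelSpec("poly0", "poly0")


def _pairs_from_profile(grid, values, cgm_stride=5):
    prof = SmoothProfile(np.asarray(grid, float), np.asarray(values, float))
    n = len(grid)
    idx = np.arange(0, n, cgm_stride)
    return MatchedPairs(
        times=prof.grid_times[idx],
        reference=prof.values[idx],
        cgm=prof.values[idx],
        segment_ids=np.zeros(idx.size, int),
        grid_index=idx,
        profile=prof,
    )


class TestPredict:
    def test_identity_parameters_reproduce_reference(self):
        pairs = _pairs_from_profile(np.arange(500.0), 120 + np.sin(np.arange(500.0) / 30))
        pred = predict_igs(
            KineticsParams(0.0), POLY0_POLY0, CalibrationParams((1.0,), (0.0,)), pairs
        )
        np.testing.assert_allclose(pred, pairs.reference, rtol=1e-12)

    def test_steady_state_median_calibration(self):
        pairs = _pairs_from_profile(np.arange(600.0), np.full(600, 100.0))
        pred = predict_igs(
            KineticsParams(3.10), POLY0_POLY0, CalibrationParams((0.95,), (7.30,)), pairs
        )
        after = pairs.times > 60.0
        np.testing.assert_allclose(pred[after], 102.3, atol=1e-6)

    def test_matches_fine_grid_quadrature_oracle(self):
        """The per-segment ZOH recursion agrees with brute-force
        convolution of the same staircase input on a 100x finer grid."""
        tau = 9.0
        grid = np.arange(0.0, 300.0)
        values = 120 + 0.8 * grid  # ramp
        pairs = _pairs_from_profile(grid, values)
        pred = predict_igs(
            KineticsParams(tau), POLY0_POLY0, CalibrationParams((1.0,), (0.0,)), pairs
        )
        # oracle: staircase input (value held over (t_{k-1}, t_k]) convolved
        # with h on a 0.01-min grid by direct summation
        fine = np.arange(0.0, 300.0, 0.01)
        staircase = values[np.minimum(np.ceil(fine - 1e-12).astype(int), 299)]
        h = np.exp(-(fine + 0.005) / tau) / tau * 0.01  # midpoint quadrature
        conv = np.convolve(staircase - values[0], h)[: fine.size] + values[0]
        oracle = conv[np.rint(pairs.times / 0.01).astype(int)]
        assert np.max(np.abs(pred - oracle)) < 0.1


class TestBic:
    def test_unit_mean_square(self):
        assert compute_bic(100.0, 100, 0) == pytest.approx(math.log(100))

    def test_direct_arithmetic(self):
        expected = 100 * math.log(4.0) + 4 * math.log(100)
        assert compute_bic(400.0, 100, 3) == pytest.approx(expected)

    def test_monotone_in_rss(self):
        b1 = compute_bic(400.0, 100, 3)
        b2 = compute_bic(800.0, 100, 3)
        assert b2 - b1 == pytest.approx(100 * math.log(2.0))

    def test_zero_rss_sentinel(self):
        with pytest.warns(UserWarning, match="BIC"):
            assert compute_bic(0.0, 100, 3) == -np.inf


class TestFitAr:
    def test_ar1_consistency(self):
        v = simulate_ar_noise(ARNoiseParams(np.array([0.5]), 1.0), 10_000, seed=0)
        ar = fit_ar([v], 1)
        assert abs(ar.alpha[0] - 0.5) < 0.02

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=10_000)
        ar = fit_ar([v], 2)
        assert np.all(np.abs(ar.alpha) < 2 / np.sqrt(v.size))

    def test_ar2_recovery_of_population_coefficients(self):
        v = simulate_ar_noise(ARNoiseParams(np.array([1.30, -0.42]), 3.19), 10_000, seed=2)
        ar = fit_ar([v], 2)
        np.testing.assert_allclose(ar.alpha, [1.30, -0.42], atol=0.03)
        assert abs(ar.sigma - 3.19) < 0.15

    def test_matches_statsmodels_on_single_segment(self):
        """Independent cross-check against a conditional-MLE AR fit."""
        sm = pytest.importorskip("statsmodels.tsa.ar_model")
        v = simulate_ar_noise(ARNoiseParams(np.array([1.30, -0.42]), 3.19), 20_000, seed=3)
        ours = fit_ar([v], 2)
        theirs = sm.AutoReg(v, lags=2, trend="n").fit()
        np.testing.assert_allclose(ours.alpha, theirs.params, atol=0.02)

    def test_rank_deficiency_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_ar([np.zeros(100)], 2)


class TestWhiten:
    def test_white_noise_passthrough(self):
        rng = np.random.default_rng(4)
        r = rng.normal(size=5_000)
        wr, alpha = whiten_residuals([r])
        assert np.all(np.abs(alpha) < 0.05)
        np.testing.assert_allclose(wr[0], r[2:], atol=0.5)

    def test_whitens_ar2_residuals(self):
        v = simulate_ar_noise(ARNoiseParams(np.array([1.30, -0.42]), 3.19), 20_000, seed=5)
        wr, _ = whiten_residuals([v])
        w = wr[0]
        n = w.size
        for lag in range(1, 6):
            acf = np.corrcoef(w[:-lag], w[lag:])[0, 1]
            assert abs(acf) < 3 / np.sqrt(n)

    def test_short_segment_contributes_nothing(self):
        rng = np.random.default_rng(6)
        long_seg = rng.normal(size=1000)
        with pytest.warns(UserWarning, match="contributes no"):
            wr, _ = whiten_residuals([long_seg, np.array([1.0, 2.0])])
        assert len(wr) == 1


class TestSelectArOrder:
    def test_ar2_residuals_select_order_two(self):
        v = simulate_ar_noise(ARNoiseParams(np.array([1.30, -0.42]), 3.19), 5_000, seed=7)
        best, bics = select_ar_order([v])
        assert best == 2
        assert set(bics) == set(range(1, 11))

    def test_orders_above_data_budget_skipped(self):
        rng = np.random.default_rng(8)
        v = rng.normal(size=45)
        _, bics = select_ar_order([v], q_max=10)
        assert max(bics) <= 4  # 45 < 10*5


class TestStepOne:
    def test_zero_noise_recovery(self, noiseless_sensor):
        sensor, pairs = noiseless_sensor
        fit = fit_step1(pairs, POLY2_POLY0)
        truth = sensor.truth
        # not exactly zero: the simulated sensor carries the kinetics
        # transient from insertion, while prediction assumes steady
        # state at each session start
        assert fit.rss_raw < 1.0
        assert abs(fit.params.kinetics.tau - truth.kinetics.tau) < 1e-3 * truth.kinetics.tau
        np.testing.assert_allclose(
            fit.params.cal.a_coeffs, truth.cal.a_coeffs, rtol=1e-3, atol=1e-5
        )
        np.testing.assert_allclose(fit.params.cal.b_coeffs, truth.cal.b_coeffs, rtol=1e-3)

    def test_identity_sensor_zero_rss(self):
        grid = np.arange(0.0, 720.0)
        values = 130 + 40 * np.sin(2 * np.pi * grid / 300.0)
        pairs = _pairs_from_profile(grid, values)
        fit = fit_step1(pairs, POLY0_POLY0)
        assert fit.rss_raw < 1e-9

    def test_noisy_tau_recovery_rate(self, design):
        """Step-1 tau estimates under realistic noise are unbiased with
        a few-minute spread (the sequential procedure's known weakness):
        most replicates land within +-2.5 min of the generating value."""
        errs = []
        n_rep = 20
        sensors = generate_cohort(CohortSpec(n_sensors=n_rep, seed=77), design)
        for sensor in sensors:
            pairs = true_reference_pairs(sensor.bg, sensor.record.cgm, design)
            fit = fit_step1(pairs, POLY2_POLY0)
            errs.append(fit.params.kinetics.tau - sensor.truth.kinetics.tau)
        errs = np.asarray(errs)
        assert np.mean(np.abs(errs) <= 2.5) >= 0.7
        assert abs(np.mean(errs)) <= 1.0

    def test_insufficient_pairs_rejected(self):
        pairs = _pairs_from_profile(np.arange(20.0), np.full(20, 120.0), cgm_stride=5)
        with pytest.raises(ValueError, match="matched pairs"):
            fit_step1(pairs, POLY2_POLY0)


class TestProcedures:
    def test_two_step_zero_noise_exact(self, noiseless_sensor):
        sensor, pairs = noiseless_sensor
        fit = two_step_identify(pairs, POLY2_POLY0)
        assert fit.params.noise.sigma < 0.01
        assert abs(fit.params.kinetics.tau - sensor.truth.kinetics.tau) < 0.01

    def test_single_step_zero_noise_matches_two_step(self, noiseless_sensor):
        sensor, pairs = noiseless_sensor
        two = two_step_identify(pairs, POLY2_POLY0)
        single = single_step_identify(pairs, POLY2_POLY0, init=two)
        assert single.rss_whitened <= two.rss_whitened + 1e-9
        assert abs(single.params.kinetics.tau - two.params.kinetics.tau) < 0.1

    def test_single_step_objective_dominance(self, design):
        """Initialized at the two-step solution, the single-step optimum
        cannot exceed the two-step whitened RSS."""
        sensors = generate_cohort(CohortSpec(n_sensors=3, seed=21), design)
        for sensor in sensors:
            pairs = true_reference_pairs(sensor.bg, sensor.record.cgm, design)
            two = two_step_identify(pairs, POLY2_POLY0)
            single = single_step_identify(pairs, POLY2_POLY0, init=two)
            assert single.rss_whitened <= two.rss_whitened + 1e-9

    def test_single_step_noise_is_stationary(self, noisy_sensor):
        _, pairs = noisy_sensor
        fit = single_step_identify(pairs, POLY2_POLY0)
        from cgmerr.error_model import ar_char_roots

        roots = ar_char_roots(fit.params.noise.alpha)
        assert np.max(np.abs(roots)) < 1.0

    def test_cv_of_estimates_present(self, noisy_sensor):
        _, pairs = noisy_sensor
        fit = two_step_identify(pairs, POLY2_POLY0)
        assert fit.cv_of_estimates is not None
        assert {"tau", "a0", "b0", "alpha1"} <= set(fit.cv_of_estimates)


def _stub_fit(rss_w, residuals=None, tau=3.0):
    params = SensorErrorParams(
        KineticsParams(tau),
        POLY0_POLY0,
        CalibrationParams((1.0,), (0.0,)),
        ARNoiseParams(np.array([0.5, 0.1]), 1.0),
    )
    r = residuals if residuals is not None else np.zeros(10)
    return FitResult(
        params=params, residuals=[r], rss_raw=float(r @ r), rss_whitened=rss_w,
        bic=None, n_used=10, converged=True,
    )


class TestCompareFits:
    def test_identical_fits(self):
        fits = [_stub_fit(5.0) for _ in range(4)]
        rep = compare_fits(fits, fits)
        assert np.all(rep.per_sensor["rss_diff"] == 0)
        assert all(v == 1.0 for v in rep.correlations.values())

    def test_sign_test_matches_exact_binomial(self):
        """Oracle: two-sided exact binomial tail computed from first
        principles with math.comb."""
        rng = np.random.default_rng(9)
        n = 40
        a = [_stub_fit(10.0, tau=float(t)) for t in rng.uniform(1, 6, n)]
        # 36 improvements, 4 regressions
        deltas = np.where(np.arange(n) < 36, -1.0, 1.0)
        b = [_stub_fit(10.0 + d, tau=float(t.params.kinetics.tau) + 0.1)
             for d, t in zip(deltas, a)]
        rep = compare_fits(a, b)
        k = 36
        tail = sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n
        expected = min(1.0, 2 * tail)
        assert rep.sign_test_pvalue == pytest.approx(expected, rel=1e-9)
        assert rep.n_improved == 36

    def test_mismatched_pairs_rejected(self):
        a = [_stub_fit(1.0, residuals=np.zeros(10))]
        b = [_stub_fit(1.0, residuals=np.zeros(12))]
        with pytest.raises(ValueError, match="mismatched"):
            compare_fits(a, b)
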