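"""Two-step and single-step estimation of the sensor error parameters.

Given matched (reference BG, CGM) pairs partitioned into contiguous
session segments, the model prediction at CGM time t_j is

    y_j(theta) = a(t_j) * [BG * h(tau)](t_j) + b(t_j)

with theta = {tau, calibration coefficients}.

**Two-step procedure.** Step 1 estimates theta by nonlinear least
squares on the raw residuals r_j = ys_j - y_j(theta). Because the
residuals are autocorrelated, a whitening filter — the inverse of an
AR(2) model fitted to the residuals — is applied before computing the
residual sum of squares entering the BIC used for model selection.
Step 2 fits AR models of order q to the raw residuals by
forward-backward least squares and selects q by BIC (order 2 in
practice).

**Single-step procedure.** All parameters (theta, alpha) are estimated
simultaneously by minimizing the sum of squared *whitened* residuals

    wr_j = r_j(theta) - sum_k alpha_k r_{j-k}(theta)

subject to AR stationarity (characteristic roots strictly inside the
unit circle; for q = 2 the open triangle alpha1+alpha2 < 1,
alpha2-alpha1 < 1, |alpha2| < 1, shrunk by a small margin). The driving
white-noise SD is the sample standard deviation of the whitened
residuals at the optimum. Lagged terms never cross segment boundaries:
the first q pairs of each segment are excluded from the sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import binomtest

from .error_model import (
    ARNoiseParams,
    CalibrationModelSpec,
    CalibrationParams,
    KineticsParams,
    SensorErrorParams,
    ar_char_roots,
    eval_calibration,
    family_n_params,
)
from .smoothing import MatchedPairs

__all__ = [
    "FitResult",
    "predict_igs",
    "fit_step1",
    "whiten_residuals",
    "compute_bic",
    "fit_ar",
    "select_ar_order",
    "two_step_identify",
    "single_step_identify",
    "compare_fits",
    "ComparisonReport",
    "params_to_dict",
]

#: Internal scaling of tau so all optimization variables are O(1).
TAU_SCALE = 10.0
DEFAULT_TAU_INIT = 7.0  # minutes
DEFAULT_TAU_BOUNDS = (0.0, 60.0)  # minutes
STABILITY_MARGIN = 1e-3
#: Fallback AR(2) initialization for the single-step procedure
#: (published population median coefficients).
AR2_FALLBACK = (1.30, -0.42)


@dataclass
class FitResult:
    """Outcome of one identification run on one sensor."""

    params: SensorErrorParams
    residuals: list  # raw residuals r_j per segment
    rss_raw: float
    rss_whitened: float | None
    bic: float | None
    n_used: int
    converged: bool
    se: dict | None = None
    cv_of_estimates: dict | None = None
    method: str = ""
    opt: object = field(default=None, repr=False)  # backend optimizer result


# ---------------------------------------------------------------------------
# Prediction


def _make_predictor(pairs: MatchedPairs):
    """Closure computing model predictions at the paired CGM times.

    The 1-min reference profile is convolved with the kinetics kernel
    per contiguous grid run (exact zero-order-hold recursion), sampled
    at the matched grid points, and passed through the calibration
    curves evaluated at the CGM times.
    """
    prof = pairs.profile
    if prof is None or len(prof) == 0:
        raise ValueError("MatchedPairs must carry a reference profile")
    gt = prof.grid_times
    gv = prof.values
    if pairs.n and (pairs.grid_index.min() < 0 or pairs.grid_index.max() >= gt.size):
        raise ValueError("grid_index outside reference coverage")
    run_edges = [(sl.start, sl.stop) for sl in prof.contiguous_runs()]
    gidx = pairs.grid_index
    t_cgm = pairs.times
    from scipy.signal import lfilter

    def predict(tau: float, spec: CalibrationModelSpec, cal: CalibrationParams):
        if tau > 0:
            phi = math.exp(-1.0 / tau)
            ig = np.empty_like(gv)
            for a, b in run_edges:
                x = gv[a:b]
                y, _ = lfilter([1.0 - phi], [1.0, -phi], x, zi=[phi * x[0]])
                ig[a:b] = y
        else:
            ig = gv
        a_t, b_t = eval_calibration(spec, cal, t_cgm)
        return a_t * ig[gidx] + b_t

    return predict


def predict_igs(
    kinetics: KineticsParams,
    spec: CalibrationModelSpec,
    cal: CalibrationParams,
    pairs: MatchedPairs,
) -> np.ndarray:
    """Model prediction y_j(theta) at each paired CGM time."""
    return _make_predictor(pairs)(kinetics.tau, spec, cal)


# ---------------------------------------------------------------------------
# Parameter packing

def _family_init(family: str, level: float) -> list[float]:
    if family == "exp":
        return [level, level, 3.0]  # initial, final, time constant (days)
    c = [0.0] * family_n_params(family)
    c[0] = level
    return c


def _family_bounds(family: str) -> tuple[list[float], list[float]]:
    n = family_n_params(family)
    lo = [-np.inf] * n
    hi = [np.inf] * n
    if family == "exp":
        lo[2] = 1e-2  # days; keep the exponential time constant positive
    return lo, hi


def _pack(spec: CalibrationModelSpec, tau: float, cal: CalibrationParams):
    return np.array([tau / TAU_SCALE, *cal.a_coeffs, *cal.b_coeffs])


def _unpack(spec: CalibrationModelSpec, x: np.ndarray):
    na = family_n_params(spec.a_family)
    nb = family_n_params(spec.b_family)
    tau = TAU_SCALE * x[0]
    cal = CalibrationParams(tuple(x[1 : 1 + na]), tuple(x[1 + na : 1 + na + nb]))
    return tau, cal


def _theta_names(spec: CalibrationModelSpec) -> list[str]:
    na = family_n_params(spec.a_family)
    nb = family_n_params(spec.b_family)
    return ["tau"] + [f"a{k}" for k in range(na)] + [f"b{k}" for k in range(nb)]


def _split_segments(values: np.ndarray, pairs: MatchedPairs) -> list[np.ndarray]:
    return [values[sl] for sl in pairs.segment_slices()]


# ---------------------------------------------------------------------------
# Step 1: kinetics + calibration by nonlinear least squares


def fit_step1(
    pairs: MatchedPairs,
    spec: CalibrationModelSpec,
    init: tuple[float, CalibrationParams] | None = None,
    tau_bounds: tuple[float, float] = DEFAULT_TAU_BOUNDS,
) -> FitResult:
    """Estimate tau and the calibration coefficients by nonlinear least
    squares on the raw residuals.

    Default initialization: tau = 7 min, a(t) = 1, b(t) = 0. tau is
    bounded (default [0, 60] min) so estimates "close to 0" remain
    feasible; all variables are scaled to O(1) internally.
    """
    n_cal = spec.n_params
    if pairs.n < n_cal + 2:
        raise ValueError(
            f"need at least {n_cal + 2} matched pairs for spec {spec.label}, "
            f"got {pairs.n}"
        )
    if init is None:
        tau0 = DEFAULT_TAU_INIT
        cal0 = CalibrationParams(
            tuple(_family_init(spec.a_family, 1.0)),
            tuple(_family_init(spec.b_family, 0.0)),
        )
    else:
        tau0, cal0 = init
    x0 = _pack(spec, tau0, cal0)
    lo_a, hi_a = _family_bounds(spec.a_family)
    lo_b, hi_b = _family_bounds(spec.b_family)
    lo = np.array([tau_bounds[0] / TAU_SCALE, *lo_a, *lo_b])
    hi = np.array([tau_bounds[1] / TAU_SCALE, *hi_a, *hi_b])
    x0 = np.clip(x0, lo, hi)
    predictor = _make_predictor(pairs)

    def resid(x):
        tau, cal = _unpack(spec, x)
        return pairs.cgm - predictor(tau, spec, cal)

    res = least_squares(
        resid, x0, bounds=(lo, hi), method="trf", gtol=1e-8, xtol=1e-12, ftol=1e-12
    )
    if res.status <= 0:
        warnings.warn("step-1 fit did not converge; best iterate returned",
                      stacklevel=2)
    tau_hat, cal_hat = _unpack(spec, res.x)
    r = res.fun  # ys - y(theta_hat)
    params = SensorErrorParams(
        KineticsParams(float(tau_hat)), spec, cal_hat, noise=None
    )
    return FitResult(
        params=params,
        residuals=_split_segments(r, pairs),
        rss_raw=float(r @ r),
        rss_whitened=None,
        bic=None,
        n_used=pairs.n,
        converged=bool(res.status > 0),
        method="step1",
        opt=res,
    )


# ---------------------------------------------------------------------------
# AR fitting, whitening and BIC


def _stabilize(alpha: np.ndarray, margin: float = STABILITY_MARGIN) -> np.ndarray:
    """Shrink the AR characteristic roots radially until the process is
    stationary with the given margin."""
    roots = ar_char_roots(alpha)
    if not roots.size:
        return alpha
    r_max = float(np.max(np.abs(roots)))
    if r_max < 1.0 - margin:
        return alpha
    s = (1.0 - margin) / r_max
    return alpha * s ** np.arange(1, alpha.size + 1)


def _ar_design(residuals, q: int):
    """Forward-backward (modified covariance) regression blocks.

    Lag products never cross segment boundaries: each segment
    contributes its own forward rows (predict r[j] from the q preceding
    samples) and backward rows (predict r[j] from the q following
    samples).
    """
    xs, ys_ = [], []
    fwd = []
    for r in residuals:
        r = np.asarray(r, dtype=float)
        n = r.size
        if n < q + 1:
            continue
        xf = np.column_stack([r[q - 1 - k : n - 1 - k] for k in range(q)])
        xb = np.column_stack([r[1 + k : n - q + 1 + k] for k in range(q)])
        xs.extend([xf, xb])
        ys_.extend([r[q:], r[:n - q]])
        fwd.append((xf, r[q:]))
    if not xs:
        raise ValueError("no segment long enough for the requested AR order")
    return np.vstack(xs), np.concatenate(ys_), fwd


def fit_ar(
    residuals,
    q: int,
    period: float = 5.0,
    stabilize: bool = True,
    details: bool = False,
):
    """Fit an AR(q) model to per-segment residual series by
    forward-backward least squares.

    The white-noise SD is the root mean square of the one-step forward
    prediction errors. A (rare) nonstationary estimate is projected
    radially just inside the unit circle when ``stabilize`` is set.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    x, y, fwd = _ar_design(residuals, q)
    alpha, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < q:
        raise np.linalg.LinAlgError("rank-deficient AR regression")
    e = np.concatenate([yf - xf @ alpha for xf, yf in fwd])
    sigma = float(np.sqrt(np.mean(e**2)))
    if stabilize:
        alpha_s = _stabilize(alpha)
        if not np.array_equal(alpha_s, alpha):
            warnings.warn("AR estimate projected into the stability region",
                          stacklevel=2)
        alpha = alpha_s
    noise = ARNoiseParams(alpha, sigma, period)
    if details:
        info = {
            "rss_forward": float(e @ e),
            "n_forward": int(e.size),
            "xtx": x.T @ x,
        }
        return noise, info
    return noise


def whiten_residuals(residuals, order: int = 2):
    """Whiten per-segment residuals with the inverse of an AR filter
    fitted to them (order 2 by default).

    Returns ``(whitened segments, alpha)``. The first ``order`` samples
    of each segment are dropped; segments shorter than ``order + 1``
    contribute nothing (with a warning).
    """
    ar = fit_ar(residuals, order, stabilize=True)
    alpha = ar.alpha
    out = []
    for r in residuals:
        r = np.asarray(r, dtype=float)
        n = r.size
        if n < order + 1:
            warnings.warn(
                f"segment of length {n} contributes no whitened residuals",
                stacklevel=2,
            )
            continue
        w = r[order:].copy()
        for k in range(1, order + 1):
            w -= alpha[k - 1] * r[order - k : n - k]
        out.append(w)
    return out, alpha


def compute_bic(rss: float, n: int, n_params: int) -> float:
    """Bayesian Information Criterion ``n*ln(rss/n) + (n_params+1)*ln(n)``.

    ``n_params`` is the calibration coefficient count N_p (the +1 added
    internally accounts for tau) or, for AR-order selection, the AR
    order q (the +1 then counts the innovation variance). ``rss`` is the
    whitened residual sum of squares and ``n`` the number of residuals
    entering it. A zero RSS returns ``-inf`` with a warning.
    """
    if n <= n_params:
        raise ValueError("n must exceed the parameter count")
    if rss <= 0:
        warnings.warn("zero RSS: BIC is -inf", stacklevel=2)
        return -np.inf
    return float(n * np.log(rss / n) + (n_params + 1) * np.log(n))


def select_ar_order(residuals, q_max: int = 10, period: float = 5.0):
    """Fit AR(q) for q = 1..q_max and select the order minimizing BIC.

    Orders requiring more data than available (pooled residual count
    below 10*q) are skipped. Returns ``(best order, {order: BIC})``.
    """
    n_pooled = int(sum(np.size(r) for r in residuals))
    bics: dict[int, float] = {}
    for q in range(1, q_max + 1):
        if n_pooled < 10 * q:
            continue
        try:
            _, info = fit_ar(residuals, q, period=period, details=True)
        except (ValueError, np.linalg.LinAlgError):
            continue
        bics[q] = compute_bic(info["rss_forward"], info["n_forward"], q)
    if not bics:
        raise ValueError("no AR order could be fitted")
    best = min(bics, key=bics.get)
    return best, bics


# ---------------------------------------------------------------------------
# Two-step identification


def _whiten_matrix(mat: np.ndarray, pairs: MatchedPairs, alpha: np.ndarray):
    """Apply the whitening filter to each column of a per-pair matrix,
    segment by segment."""
    order = alpha.size
    out = []
    for sl in pairs.segment_slices():
        block = mat[sl]
        n = block.shape[0]
        if n < order + 1:
            continue
        w = block[order:].copy()
        for k in range(1, order + 1):
            w -= alpha[k - 1] * block[order - k : n - k]
        out.append(w)
    return np.vstack(out) if out else np.empty((0, mat.shape[1]))


def _cv_from_se(se: dict, values: dict) -> dict:
    cv = {}
    for k, s in se.items():
        v = abs(values.get(k, np.nan))
        cv[k] = float(s / v) if v > 0 else np.inf
    return cv


def params_to_dict(fit: FitResult) -> dict:
    """Flatten a fit's parameter estimates into named scalars."""
    p = fit.params
    d = {"tau": p.kinetics.tau}
    for i, c in enumerate(p.cal.a_coeffs):
        d[f"a{i}"] = c
    for i, c in enumerate(p.cal.b_coeffs):
        d[f"b{i}"] = c
    if p.noise is not None:
        for i, c in enumerate(p.noise.alpha):
            d[f"alpha{i + 1}"] = float(c)
        d["sigma"] = p.noise.sigma
    return d


def two_step_identify(
    pairs: MatchedPairs,
    spec: CalibrationModelSpec,
    q: int = 2,
    whiten_order: int = 2,
) -> FitResult:
    """Sequential identification: step-1 nonlinear least squares for
    (tau, calibration), whitening + BIC of the whitened RSS for model
    selection, then a forward-backward AR(q) fit to the raw step-1
    residuals for the noise block.

    Approximate standard errors come from the Gauss-Markov formula on
    the whitened Jacobian at the step-1 optimum (and the AR regression
    for the noise coefficients); `cv_of_estimates` is se / |estimate|.
    """
    s1 = fit_step1(pairs, spec)
    wr_segs, alpha_w = whiten_residuals(s1.residuals, whiten_order)
    wr = np.concatenate(wr_segs) if wr_segs else np.empty(0)
    rss_w = float(wr @ wr)
    n_w = int(wr.size)
    bic = compute_bic(rss_w, n_w, spec.n_params) if n_w > spec.n_params else None
    ar, info = fit_ar(s1.residuals, q, period=_pairs_period(pairs), details=True)
    params = replace(s1.params, noise=ar)

    se: dict[str, float] = {}
    names = _theta_names(spec)
    jac = np.asarray(s1.opt.jac)
    jac_theta = jac.copy()
    jac_theta[:, 0] /= TAU_SCALE  # unscale d/dtau
    jw = _whiten_matrix(jac_theta, pairs, alpha_w)
    try:
        cov = ar.sigma**2 * np.linalg.pinv(jw.T @ jw)
        for name, s2 in zip(names, np.diag(cov)):
            se[name] = float(np.sqrt(max(s2, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        pass
    try:
        cov_a = ar.sigma**2 * np.linalg.pinv(info["xtx"])
        for i, s2 in enumerate(np.diag(cov_a)):
            se[f"alpha{i + 1}"] = float(np.sqrt(max(s2, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    values = params_to_dict(replace(s1, params=params))
    return FitResult(
        params=params,
        residuals=s1.residuals,
        rss_raw=s1.rss_raw,
        rss_whitened=rss_w,
        bic=bic,
        n_used=n_w,
        converged=s1.converged,
        se=se or None,
        cv_of_estimates=_cv_from_se(se, values) if se else None,
        method="two-step",
        opt=s1.opt,
    )


def _pairs_period(pairs: MatchedPairs) -> float:
    for sl in pairs.segment_slices():
        t = pairs.times[sl]
        if t.size > 1:
            return float(np.median(np.diff(t)))
    return 5.0


# ---------------------------------------------------------------------------
# Single-step identification


def _whitened_fun(pairs: MatchedPairs, spec: CalibrationModelSpec, q: int):
    predictor = _make_predictor(pairs)
    seg_slices = list(pairs.segment_slices())
    ys = pairs.cgm

    def whitened(x):
        tau, cal = _unpack(spec, x[:-q])
        alpha = x[-q:]
        r = ys - predictor(max(tau, 0.0), spec, cal)
        out = []
        for sl in seg_slices:
            rs = r[sl]
            n = rs.size
            if n < q + 1:
                continue
            w = rs[q:].copy()
            for k in range(1, q + 1):
                w -= alpha[k - 1] * rs[q - k : n - k]
            out.append(w)
        return np.concatenate(out) if out else np.empty(0)

    return whitened, predictor


def _numeric_jacobian(fun, x: np.ndarray) -> np.ndarray:
    f0 = fun(x)
    jac = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = 1e-6 * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        jac[:, i] = (fun(xp) - f0) / h
    return jac


def single_step_identify(
    pairs: MatchedPairs,
    spec: CalibrationModelSpec,
    q: int = 2,
    init: FitResult | None = None,
    stability_margin: float = STABILITY_MARGIN,
) -> FitResult:
    """Joint identification of (tau, calibration, AR coefficients) by
    constrained minimization of the whitened residual sum of squares.

    ``init`` is normally the sensor's own two-step fit (run internally
    when omitted): theta starts at the two-step solution and alpha at
    the two-step AR fit, which also guarantees the optimum cannot be
    worse than the two-step whitened RSS — if the constrained optimizer
    ends above its initialization, the initialization is kept and the
    fit flagged as not converged. The white-noise SD is the sample
    standard deviation of the whitened residuals at the optimum.
    """
    if init is None:
        init = two_step_identify(pairs, spec, q=q)
    if init.params.cal_spec != spec:
        raise ValueError("init was fitted with a different calibration spec")
    if init.params.noise is not None and init.params.noise.order == q:
        alpha0 = np.asarray(init.params.noise.alpha, dtype=float)
    elif q == 2:
        alpha0 = np.array(AR2_FALLBACK)
    else:
        alpha0 = fit_ar(init.residuals, q).alpha
    # keep the starting point strictly inside the shrunk stability region
    margin = stability_margin
    for _ in range(200):
        roots = ar_char_roots(alpha0)
        if not roots.size or np.max(np.abs(roots)) < 1.0 - 2 * margin:
            break
        alpha0 = alpha0 * (0.99 ** np.arange(1, q + 1))

    x0 = np.concatenate(
        [_pack(spec, init.params.kinetics.tau, init.params.cal), alpha0]
    )
    whitened, predictor = _whitened_fun(pairs, spec, q)

    def f(x):
        w = whitened(x)
        return float(w @ w)

    lo_a, hi_a = _family_bounds(spec.a_family)
    lo_b, hi_b = _family_bounds(spec.b_family)
    bounds = [(DEFAULT_TAU_BOUNDS[0] / TAU_SCALE, DEFAULT_TAU_BOUNDS[1] / TAU_SCALE)]
    bounds += list(zip(lo_a, hi_a)) + list(zip(lo_b, hi_b))
    n_theta = 1 + spec.n_params
    if q == 2:
        bounds += [(-2.0 + margin, 2.0 - margin), (-1.0 + margin, 1.0 - margin)]
        constraints = [
            {"type": "ineq",
             "fun": lambda x: 1.0 - margin - (x[n_theta] + x[n_theta + 1])},
            {"type": "ineq",
             "fun": lambda x: 1.0 - margin - (x[n_theta + 1] - x[n_theta])},
        ]
    else:
        bounds += [(None, None)] * q
        constraints = [
            {"type": "ineq",
             "fun": lambda x: 1.0 - margin - np.max(np.abs(ar_char_roots(x[-q:])))}
        ]
    bounds = [
        (None if lo is None or not np.isfinite(lo) else float(lo),
         None if hi is None or not np.isfinite(hi) else float(hi))
        for lo, hi in bounds
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = minimize(
            f,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 300, "ftol": 1e-12},
        )
    f0 = f(x0)
    took_opt = np.isfinite(res.fun) and res.fun <= f0
    x_hat = res.x if took_opt else x0
    converged = bool(res.success and took_opt)
    if not converged and not took_opt:
        warnings.warn("single-step optimizer did not improve on its "
                      "initialization; initialization kept", stacklevel=2)

    tau_hat, cal_hat = _unpack(spec, x_hat[:-q])
    alpha_hat = _stabilize(np.asarray(x_hat[-q:], dtype=float), margin / 2)
    w = whitened(x_hat)
    rss_w = float(w @ w)
    n_w = int(w.size)
    sigma = float(np.std(w, ddof=1)) if n_w > 1 else 0.0
    noise = ARNoiseParams(alpha_hat, sigma, _pairs_period(pairs))
    params = SensorErrorParams(
        KineticsParams(max(float(tau_hat), 0.0)), spec, cal_hat, noise=noise
    )
    r = pairs.cgm - predictor(max(tau_hat, 0.0), spec, cal_hat)
    n_params_tot = spec.n_params + q
    bic = compute_bic(rss_w, n_w, n_params_tot) if n_w > n_params_tot else None

    names = _theta_names(spec) + [f"alpha{k + 1}" for k in range(q)]
    se: dict[str, float] = {}
    try:
        jac = _numeric_jacobian(whitened, x_hat)
        jac[:, 0] /= TAU_SCALE
        cov = sigma**2 * np.linalg.pinv(jac.T @ jac)
        for name, s2 in zip(names, np.diag(cov)):
            se[name] = float(np.sqrt(max(s2, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        pass
    fit = FitResult(
        params=params,
        residuals=_split_segments(r, pairs),
        rss_raw=float(r @ r),
        rss_whitened=rss_w,
        bic=bic,
        n_used=n_w,
        converged=converged,
        se=se or None,
        method="single-step",
        opt=res,
    )
    fit.cv_of_estimates = _cv_from_se(se, params_to_dict(fit)) if se else None
    return fit


# ---------------------------------------------------------------------------
# Procedure comparison


@dataclass
class ComparisonReport:
    """Paired comparison of two identification procedures on a cohort."""

    per_sensor: object  # pandas.DataFrame
    sign_test_pvalue: float
    n_improved: int
    n_nonzero: int
    correlations: dict


def compare_fits(fits_a, fits_b, pairs_list=None) -> ComparisonReport:
    """Compare two sets of fits on the same sensors.

    Reports per sensor the RMSE of each fit's raw residuals and the
    whitened-RSS difference (b - a), an exact binomial sign test on the
    RSS differences across the cohort, and per-parameter Pearson
    correlations between the two procedures' estimates.
    """
    import pandas as pd

    if isinstance(fits_a, FitResult):
        fits_a, fits_b = [fits_a], [fits_b]
    if len(fits_a) != len(fits_b):
        raise ValueError("fit collections must have equal length")
    rows = []
    pa, pb = [], []
    for i, (fa, fb) in enumerate(zip(fits_a, fits_b)):
        ra = np.concatenate(fa.residuals) if fa.residuals else np.empty(0)
        rb = np.concatenate(fb.residuals) if fb.residuals else np.empty(0)
        if ra.size != rb.size:
            raise ValueError("fits were computed on mismatched pairs")
        if pairs_list is not None and pairs_list[i].n != ra.size:
            raise ValueError("fits were computed on mismatched pairs")
        rows.append(
            {
                "sensor": i,
                "rmse_a": float(np.sqrt(np.mean(ra**2))) if ra.size else np.nan,
                "rmse_b": float(np.sqrt(np.mean(rb**2))) if rb.size else np.nan,
                "rss_whitened_a": fa.rss_whitened,
                "rss_whitened_b": fb.rss_whitened,
            }
        )
        pa.append(params_to_dict(fa))
        pb.append(params_to_dict(fb))
    df = pd.DataFrame(rows)
    df["rss_diff"] = df["rss_whitened_b"] - df["rss_whitened_a"]
    diffs = df["rss_diff"].to_numpy(dtype=float)
    nonzero = diffs[diffs != 0]
    n_improved = int(np.sum(diffs < 0))
    if nonzero.size:
        pval = float(binomtest(int(np.sum(nonzero < 0)), nonzero.size, 0.5).pvalue)
    else:
        pval = 1.0
    da, db = pd.DataFrame(pa), pd.DataFrame(pb)
    corr = {}
    for col in sorted(set(da.columns) & set(db.columns)):
        xa, xb = da[col].to_numpy(float), db[col].to_numpy(float)
        if np.allclose(xa, xb):
            corr[col] = 1.0
        elif np.std(xa) == 0 or np.std(xb) == 0:
            corr[col] = np.nan
        else:
            corr[col] = float(np.corrcoef(xa, xb)[0, 1])
    return ComparisonReport(
        per_sensor=df,
        sign_test_pvalue=pval,
        n_improved=n_improved,
        n_nonzero=int(nonzero.size),
        correlations=corr,
    )
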