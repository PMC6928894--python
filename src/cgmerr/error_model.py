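"""Generative error model of a factory-calibrated CGM sensor.

A continuous glucose monitoring (CGM) sensor reads interstitial glucose
(IG), not blood glucose (BG), and its output is distorted by three
error sources applied in series:

A. **Plasma-to-interstitium kinetics** — first-order diffusion with
   impulse response ``h(t) = (1/tau) * exp(-t/tau)``, delaying and
   low-pass filtering BG into IG.
B. **Calibration error** — a slowly varying multiplicative gain ``a(t)``
   and additive offset ``b(t)`` over the 10-day sensor lifetime:
   ``IGs(t) = a(t) * IG(t) + b(t)``.
C. **Measurement noise** — additive autoregressive (AR) noise ``v(t)``
   at the CGM sampling period, driven by zero-mean white noise of
   standard deviation ``sigma``: ``CGM(t) = IGs(t) + v(t)``.

This module defines the parameter containers for each block and the
forward operations that compose them into a simulated CGM trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "CGM_DISPLAY_RANGE",
    "CALIBRATION_FAMILIES",
    "GlucoseTrace",
    "KineticsParams",
    "CalibrationModelSpec",
    "CalibrationParams",
    "ARNoiseParams",
    "SensorErrorParams",
    "ar_char_roots",
    "bg_to_ig",
    "eval_calibration",
    "apply_calibration",
    "simulate_ar_noise",
    "simulate_cgm",
]

#: Display range of the sensor receiver; readings outside it saturate.
CGM_DISPLAY_RANGE = (40.0, 400.0)

#: Candidate function families for the calibration gain/offset curves.
CALIBRATION_FAMILIES = ("poly0", "poly1", "poly2", "poly3", "exp")

_FAMILY_N_PARAMS = {"poly0": 1, "poly1": 2, "poly2": 3, "poly3": 4, "exp": 3}

MINUTES_PER_DAY = 1440.0


def _as_float_array(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class GlucoseTrace:
    """A timestamped glucose series.

    Parameters
    ----------
    times
        Minutes since sensor insertion, strictly increasing.
    values
        Glucose concentration in mg/dL, finite and positive.
    segment_ids
        Integer labels grouping contiguous runs of samples (e.g. one
        clinical session). Defaults to a single segment.
    saturated
        Optional boolean mask flagging samples clipped to the display
        range by the receiver.
    """

    times: np.ndarray
    values: np.ndarray
    segment_ids: np.ndarray | None = None
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape != self.times.shape:
            raise ValueError("times and values must have matching shapes")
        if self.segment_ids is None:
            self.segment_ids = np.zeros(self.times.size, dtype=int)
        else:
            self.segment_ids = np.asarray(self.segment_ids, dtype=int).ravel()
            if self.segment_ids.shape != self.times.shape:
                raise ValueError("segment_ids must match times in shape")
        if self.saturated is not None:
            self.saturated = np.asarray(self.saturated, dtype=bool).ravel()
            if self.saturated.shape != self.times.shape:
                raise ValueError("saturated mask must match times in shape")
        if self.times.size:
            if not np.all(np.isfinite(self.times)):
                raise ValueError("times must be finite")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")
            if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
                raise ValueError("values must be finite and positive")

    def __len__(self) -> int:
        return self.times.size

    def iter_segments(self) -> Iterator[slice]:
        """Yield slices over maximal runs of equal ``segment_ids``."""
        if not len(self):
            return
        breaks = np.flatnonzero(np.diff(self.segment_ids) != 0) + 1
        edges = [0, *breaks.tolist(), len(self)]
        for a, b in zip(edges[:-1], edges[1:]):
            yield slice(a, b)

    def segment_step(self, sl: slice, tol: float = 1e-9) -> float | None:
        """Uniform sampling step of a segment, or ``None`` for singletons.

        Raises ``ValueError`` if the segment grid is not uniform.
        """
        t = self.times[sl]
        if t.size < 2:
            return None
        d = np.diff(t)
        if np.any(np.abs(d - d[0]) > tol):
            raise ValueError("segment is not uniformly sampled")
        return float(d[0])


@dataclass(frozen=True)
class KineticsParams:
    """BG-to-IG diffusion time constant ``tau`` in minutes (``tau = 0``
    means no delay)."""

    tau: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.tau) or self.tau < 0:
            raise ValueError("tau must be finite and >= 0")


@dataclass(frozen=True)
class CalibrationModelSpec:
    """One of the 5 x 5 candidate pairs of function families for the
    calibration gain a(t) and offset b(t)."""

    a_family: str
    b_family: str

    def __post_init__(self) -> None:
        for fam in (self.a_family, self.b_family):
            if fam not in CALIBRATION_FAMILIES:
                raise ValueError(f"unknown calibration family {fam!r}")

    @property
    def n_params(self) -> int:
        """Total calibration coefficient count N_p."""
        return _FAMILY_N_PARAMS[self.a_family] + _FAMILY_N_PARAMS[self.b_family]

    @property
    def label(self) -> str:
        return f"({self.a_family},{self.b_family})"

    @staticmethod
    def from_label(label: str) -> "CalibrationModelSpec":
        a, b = label.strip("() ").split(",")
        return CalibrationModelSpec(a.strip(), b.strip())


def family_n_params(family: str) -> int:
    return _FAMILY_N_PARAMS[family]


@dataclass(frozen=True)
class CalibrationParams:
    """Coefficients of the gain and offset curves.

    Polynomial coefficients are in ascending order of powers of time
    expressed in **days** since insertion, so the k-th coefficient has
    units days^-k. The exponential family takes (initial value, final
    value, time constant in days).
    """

    a_coeffs: tuple[float, ...]
    b_coeffs: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "a_coeffs", tuple(float(c) for c in self.a_coeffs))
        object.__setattr__(self, "b_coeffs", tuple(float(c) for c in self.b_coeffs))


def ar_char_roots(alpha: np.ndarray) -> np.ndarray:
    """Roots of ``z^q - alpha_1 z^(q-1) - ... - alpha_q``.

    The AR process is stationary iff all roots are strictly inside the
    unit circle.
    """
    alpha = _as_float_array(alpha) if np.size(alpha) else np.empty(0)
    if alpha.size == 0:
        return np.empty(0, dtype=complex)
    return np.roots(np.concatenate([[1.0], -alpha]))


@dataclass
class ARNoiseParams:
    """Autoregressive measurement-noise parameters.

    ``alpha`` are the AR coefficients (possibly empty for white noise),
    ``sigma`` the standard deviation of the driving white noise in
    mg/dL, and ``period`` the sampling period T in minutes.
    """

    alpha: np.ndarray
    sigma: float
    period: float = 5.0

    def __post_init__(self) -> None:
        self.alpha = (
            _as_float_array(self.alpha) if np.size(self.alpha) else np.empty(0)
        )
        self.sigma = float(self.sigma)
        if not math.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be finite and >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")
        roots = ar_char_roots(self.alpha)
        if roots.size and np.max(np.abs(roots)) >= 1.0:
            raise ValueError(
                "nonstationary AR coefficients: characteristic root on or "
                "outside the unit circle"
            )

    @property
    def order(self) -> int:
        return int(self.alpha.size)


@dataclass
class SensorErrorParams:
    """Complete parameter set of one sensor: kinetics, calibration and
    noise blocks. ``noise`` may be ``None`` for the noiseless part of
    the model (e.g. after the first identification step)."""

    kinetics: KineticsParams
    cal_spec: CalibrationModelSpec
    cal: CalibrationParams
    noise: ARNoiseParams | None = None


# ---------------------------------------------------------------------------
# Block A: BG-to-IG kinetics


def bg_to_ig(bg: GlucoseTrace, kinetics: KineticsParams) -> GlucoseTrace:
    """Filter a BG trace through the first-order diffusion kinetics.

    Discretized per segment by the exact zero-order-hold recursion

        IG[k] = phi * IG[k-1] + (1 - phi) * BG[k],   phi = exp(-dt/tau)

    with steady-state initial condition ``IG[0] = BG[0]``. ``tau = 0``
    returns the input unchanged. Each segment must be uniformly sampled.
    """
    tau = kinetics.tau
    if tau == 0.0:
        return GlucoseTrace(
            bg.times.copy(), bg.values.copy(), bg.segment_ids.copy()
        )
    out = np.empty_like(bg.values)
    for sl in bg.iter_segments():
        x = bg.values[sl]
        step = bg.segment_step(sl)
        if step is None:
            out[sl] = x
            continue
        phi = math.exp(-step / tau)
        y, _ = lfilter([1.0 - phi], [1.0, -phi], x, zi=[phi * x[0]])
        out[sl] = y
    return GlucoseTrace(bg.times.copy(), out, bg.segment_ids.copy())


# ---------------------------------------------------------------------------
# Block B: calibration error


def _eval_family(family: str, coeffs, t_days: np.ndarray) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != _FAMILY_N_PARAMS[family]:
        raise ValueError(
            f"family {family!r} takes {_FAMILY_N_PARAMS[family]} coefficients, "
            f"got {coeffs.size}"
        )
    if family == "exp":
        p0, p1, p2 = coeffs
        if p2 <= 0:
            raise ValueError("exponential time constant must be positive")
        return p1 + (p0 - p1) * np.exp(-t_days / p2)
    return np.polynomial.polynomial.polyval(t_days, coeffs)


def eval_calibration(
    spec: CalibrationModelSpec, cal: CalibrationParams, times_min
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the gain a(t) and offset b(t) at times given in minutes.

    The function argument is time in days since insertion, so the
    polynomial coefficients carry days^-k units.
    """
    t = _as_float_array(times_min)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    t_days = t / MINUTES_PER_DAY
    a = _eval_family(spec.a_family, cal.a_coeffs, t_days)
    b = _eval_family(spec.b_family, cal.b_coeffs, t_days)
    return np.broadcast_to(a, t.shape).astype(float), np.broadcast_to(
        b, t.shape
    ).astype(float)


def apply_calibration(
    ig: GlucoseTrace, spec: CalibrationModelSpec, cal: CalibrationParams
) -> GlucoseTrace:
    """Distort an IG trace by the calibration error: IGs = a(t)*IG + b(t)."""
    a, b = eval_calibration(spec, cal, ig.times)
    return GlucoseTrace(ig.times.copy(), a * ig.values + b, ig.segment_ids.copy())


# ---------------------------------------------------------------------------
# Block C: autoregressive measurement noise


def simulate_ar_noise(
    noise: ARNoiseParams, n: int, seed=None, burn_in: int = 500
) -> np.ndarray:
    """Draw ``n`` samples of the stationary AR noise process v(t).

    The process is driven by zero-mean Gaussian white noise with SD
    ``sigma``; ``burn_in`` initial samples are discarded so the output
    is approximately stationary. Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise.sigma == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, noise.sigma, size=n + burn_in)
    if noise.order == 0:
        return w[burn_in:]
    v = lfilter([1.0], np.concatenate([[1.0], -noise.alpha]), w)
    return v[burn_in:]


# ---------------------------------------------------------------------------
# Full pipeline


def simulate_cgm(
    bg: GlucoseTrace,
    params: SensorErrorParams,
    cgm_period: float = 5.0,
    seed=None,
    burn_in: int = 500,
) -> GlucoseTrace:
    """Simulate a CGM trace from a BG profile: kinetics -> calibration ->
    downsampling to the CGM period -> additive AR noise -> receiver
    clipping to [40, 400] mg/dL (clipped samples flagged via the
    ``saturated`` mask).

    ``bg`` must be uniformly sampled (1-min grid recommended) and
    ``cgm_period`` an integer multiple of its step.
    """
    if len(bg) < 2:
        raise ValueError("bg must contain at least two samples")
    d = np.diff(bg.times)
    if np.any(np.abs(d - d[0]) > 1e-9):
        raise ValueError("bg must be uniformly sampled")
    step = float(d[0])
    ratio = cgm_period / step
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError("cgm_period must be an integer multiple of the bg step")

    ig = bg_to_ig(bg, params.kinetics)
    igs = apply_calibration(ig, params.cal_spec, params.cal)
    idx = np.arange(0, len(bg), k)
    y = igs.values[idx].copy()
    if params.noise is not None and params.noise.sigma > 0:
        y = y + simulate_ar_noise(params.noise, idx.size, seed=seed, burn_in=burn_in)
    lo, hi = CGM_DISPLAY_RANGE
    saturated = (y <= lo) | (y >= hi)
    y = np.clip(y, lo, hi)
    return GlucoseTrace(bg.times[idx].copy(), y, saturated=saturated)
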