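"""Synthetic study-data generation with known ground truth.

The published study design this package targets pairs a 10-day CGM
wear (5-min sampling) with three 12-h in-clinic sessions (beginning /
middle / end of wear, e.g. days 2, 4 and 10) in which reference BG is
drawn every 15 min with ~2% coefficient-of-variation analyzer noise,
and meals are manipulated to induce large glycemic excursions. This
module emulates that design: it generates smooth, physiologically
plausible BG profiles, samples the reference schedule, and composes the
forward error model into complete synthetic sensor cohorts whose
generating parameters are known, so that identification can be scored
by parameter recovery.

The BG construction is a sum of logistic-rise x exponential-decay meal
kernels over a constant overnight baseline, with occasional nocturnal
dips; it is smooth by construction (so the Tikhonov smoother's
assumptions hold) and confined to [50, 350] mg/dL so that receiver
saturation occurs only through measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .error_model import (
    ARNoiseParams,
    CalibrationModelSpec,
    CalibrationParams,
    GlucoseTrace,
    KineticsParams,
    SensorErrorParams,
    ar_char_roots,
    simulate_cgm,
)
from .preprocessing import SensorRecord
from .smoothing import ReferenceSamples

__all__ = [
    "StudyDesign",
    "BgSettings",
    "CohortSpec",
    "SyntheticSensor",
    "reference_sensor_params",
    "calibration_population_sd",
    "selection_study_population",
    "generate_bg",
    "sample_reference",
    "generate_cohort",
]

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class StudyDesign:
    """Clinical sampling design of a sensor-wear study."""

    wear_days: float = 10.0
    session_start_days: tuple[int, ...] = (2, 4, 10)
    session_duration_h: float = 12.0
    ref_period_min: float = 15.0
    cgm_period_min: float = 5.0

    def __post_init__(self) -> None:
        bounds = self.session_bounds()
        for (a0, a1), (b0, b1) in zip(bounds[:-1], bounds[1:]):
            if b0 < a1:
                raise ValueError("sessions must not overlap")
        if bounds and bounds[-1][1] > self.wear_days * MINUTES_PER_DAY + 1e-9:
            raise ValueError("sessions must lie within the wear period")

    def session_bounds(self) -> list[tuple[float, float]]:
        """(start, end) of each session in minutes since insertion; a
        session on nominal day d starts at the beginning of that day."""
        dur = self.session_duration_h * 60.0
        return [
            ((d - 1) * MINUTES_PER_DAY, (d - 1) * MINUTES_PER_DAY + dur)
            for d in self.session_start_days
        ]


@dataclass(frozen=True)
class BgSettings:
    """Knobs of the BG-profile generator (times in minutes, glucose in
    mg/dL unless noted)."""

    baseline_range: tuple[float, float] = (110.0, 140.0)
    meal_hours: tuple[float, ...] = (7.5, 12.5, 19.0)
    meal_time_sd_h: float = 0.75
    meal_amplitude: tuple[float, float] = (60.0, 140.0)
    rise_minutes: tuple[float, float] = (30.0, 60.0)
    decay_minutes: tuple[float, float] = (60.0, 120.0)
    dip_probability: float = 0.3
    dip_hour: float = 3.5
    dip_hour_sd: float = 0.5
    dip_depth: tuple[float, float] = (40.0, 55.0)
    bounds: tuple[float, float] = (50.0, 350.0)


def _kernel(t: np.ndarray, t0: float, s: float, tau_d: float) -> np.ndarray:
    """Smooth excursion kernel: logistic rise times exponential decay,
    normalized to unit peak. Requires s < tau_d so the tail vanishes."""
    u = t - t0
    # log-space evaluation avoids overflow of exp(-u/tau_d) for u << 0
    log_g = -np.logaddexp(0.0, -u / s) - u / tau_d
    u_star = s * math.log(tau_d / s - 1.0)
    log_peak = -math.log1p(math.exp(-u_star / s)) - u_star / tau_d
    return np.exp(log_g - log_peak)


def generate_bg(
    duration_days: float = 10.0,
    seed=None,
    settings: BgSettings | None = None,
) -> GlucoseTrace:
    """Generate a smooth BG profile on a 1-min grid.

    Three meal-like excursions per day (randomized time, amplitude,
    rise and decay) over a constant baseline, plus occasional nocturnal
    dips toward 60-70 mg/dL. Deterministic for a fixed seed.
    """
    if duration_days <= 0:
        raise ValueError("duration_days must be positive")
    st = settings or BgSettings()
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_days * MINUTES_PER_DAY, 1.0)
    v = np.full(t.size, rng.uniform(*st.baseline_range))
    for day in range(int(math.ceil(duration_days))):
        for h_mu in st.meal_hours:
            t0 = (day * 24.0 + rng.normal(h_mu, st.meal_time_sd_h)) * 60.0
            amp = rng.uniform(*st.meal_amplitude)
            rise = rng.uniform(*st.rise_minutes)
            tau_d = rng.uniform(*st.decay_minutes)
            v += amp * _kernel(t, t0, rise / 4.4, tau_d)
        if rng.uniform() < st.dip_probability:
            t0 = (day * 24.0 + rng.normal(st.dip_hour, st.dip_hour_sd)) * 60.0
            depth = rng.uniform(*st.dip_depth)
            tau_d = rng.uniform(*st.decay_minutes)
            v -= depth * _kernel(t, t0, 15.0 / 4.4, tau_d)
    np.clip(v, *st.bounds, out=v)  # safety net; construction stays inside
    return GlucoseTrace(t, v)


def sample_reference(
    bg: GlucoseTrace,
    design: StudyDesign,
    cv: float = 0.02,
    seed=None,
) -> ReferenceSamples:
    """Sample the BG profile on the clinical reference schedule and add
    analyzer noise with SD = cv * value.

    Sampling is every ``ref_period_min`` within each session, inclusive
    of the session start and exclusive of its end (48 samples for a
    12-h session at 15 min).
    """
    rng = np.random.default_rng(seed)
    step = bg.times[1] - bg.times[0] if len(bg) > 1 else 1.0
    times, values = [], []
    for t0, t1 in design.session_bounds():
        ts = np.arange(t0, t1 - 1e-9, design.ref_period_min)
        idx = np.rint((ts - bg.times[0]) / step).astype(int)
        if np.any(idx < 0) or np.any(idx >= len(bg)):
            raise ValueError("bg profile does not cover all sessions")
        times.append(ts)
        values.append(bg.values[idx])
    t = np.concatenate(times)
    y = np.concatenate(values)
    if cv > 0:
        y = y + rng.normal(0.0, cv * y)
    return ReferenceSamples(t, np.maximum(y, 1.0), cv=cv if cv > 0 else 0.02)


def reference_sensor_params() -> SensorErrorParams:
    """Population-median parameter set of a 10-day factory-calibrated
    sensor under the optimal model (poly2 gain, constant offset, AR(2)
    noise): tau = 3.78 min, a(t) = 0.95 + 0.004 t - 0.000 t^2 (t in
    days), b = 6.35 mg/dL, alpha = (1.30, -0.42), sigma = 3.19 mg/dL at
    a 5-min period."""
    return SensorErrorParams(
        kinetics=KineticsParams(3.78),
        cal_spec=CalibrationModelSpec("poly2", "poly0"),
        cal=CalibrationParams((0.95, 0.004, 0.000), (6.35,)),
        noise=ARNoiseParams(np.array([1.30, -0.42]), 3.19, 5.0),
    )


def calibration_population_sd() -> dict[str, float]:
    """Across-sensor SDs of the calibration coefficients implied by the
    reported population interquartile ranges (IQR / 1.349, normal
    reading)."""
    return {"a0": 0.126, "a1": 0.049, "a2": 0.0045, "b0": 6.03}


def selection_study_population(a_order: int) -> dict:
    """Calibration-coefficient population for model-selection recovery
    studies.

    The generating family's highest-order drift coefficient is drawn at
    identifiable magnitude — random sign, magnitude uniform on a range
    matching the upper spread individual sensors exhibit — while the
    remaining coefficients use the population SDs. A population centred
    on the median values would express no highest-order drift at all
    (the median quadratic coefficient is zero), making the generating
    family indistinguishable from a lower-order one and a selection
    study meaningless.
    """
    pop = calibration_population_sd()
    jitter: dict = {"a0": pop["a0"], "b0": pop["b0"]}
    if a_order >= 1:
        jitter["a1"] = pop["a1"]
    if a_order >= 2:
        jitter["a2"] = ("mag_uniform", 0.005, 0.012)
    if a_order == 1:
        jitter["a1"] = ("mag_uniform", 0.03, 0.08)
    return jitter


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort.

    ``base`` holds the per-parameter central values (defaults to the
    published population medians); ``jitter`` maps parameter names
    ("tau", "a0".."a3", "b0".."b3", "alpha1", "alpha2", "sigma") to
    across-sensor SDs (tau is drawn log-normally with the given SD of
    log tau; AR coefficients are redrawn until stationary). ``seed`` is
    the master seed: per-sensor seeds are spawned deterministically.
    """

    n_sensors: int = 40
    base: SensorErrorParams | None = None
    jitter: dict | None = None
    bg_settings: BgSettings = field(default_factory=BgSettings)
    cv: float = 0.02
    seed: int = 0


@dataclass
class SyntheticSensor:
    """One simulated sensor: study record, hidden truth, and the true
    BG profile (for recovery studies driven by the true reference)."""

    record: SensorRecord
    truth: SensorErrorParams
    bg: GlucoseTrace


def _calibration_is_physical(
    base: SensorErrorParams, a, b, wear_days: float
) -> bool:
    """Independently drawn coefficients can compose into a gain curve
    that collapses or explodes over the wear period (the real
    population's coefficients are correlated); such draws are
    rejected."""
    from .error_model import eval_calibration

    t = np.linspace(0.0, wear_days * MINUTES_PER_DAY, 50)
    gain, offset = eval_calibration(
        base.cal_spec, CalibrationParams(tuple(a), tuple(b)), t
    )
    return (
        float(gain.min()) > 0.3
        and float(gain.max()) < 2.5
        and float(np.abs(offset).max()) < 25.0
    )


def _draw_params(
    base: SensorErrorParams, jitter: dict | None, rng, wear_days: float = 10.0
) -> SensorErrorParams:
    if not jitter:
        return base
    tau = base.kinetics.tau
    if "tau" in jitter:
        tau = float(np.exp(rng.normal(np.log(tau), jitter["tau"])))
    def draw(center: float, how) -> float:
        if isinstance(how, tuple):
            kind, lo, hi = how
            if kind != "mag_uniform":
                raise ValueError(f"unknown jitter distribution {kind!r}")
            return float(rng.choice([-1.0, 1.0]) * rng.uniform(lo, hi))
        return float(rng.normal(center, how))

    for _ in range(200):
        a = list(base.cal.a_coeffs)
        b = list(base.cal.b_coeffs)
        for i in range(len(a)):
            if f"a{i}" in jitter:
                a[i] = draw(a[i], jitter[f"a{i}"])
        for i in range(len(b)):
            if f"b{i}" in jitter:
                b[i] = draw(b[i], jitter[f"b{i}"])
        if _calibration_is_physical(base, a, b, wear_days):
            break
    noise = base.noise
    if noise is not None:
        alpha = np.asarray(noise.alpha, float).copy()
        sigma = noise.sigma
        if any(f"alpha{k + 1}" in jitter for k in range(alpha.size)):
            for _ in range(100):
                cand = np.array(
                    [
                        rng.normal(c, jitter.get(f"alpha{k + 1}", 0.0))
                        for k, c in enumerate(noise.alpha)
                    ]
                )
                roots = ar_char_roots(cand)
                if not roots.size or np.max(np.abs(roots)) < 0.95:
                    alpha = cand
                    break
        if "sigma" in jitter:
            sigma = float(abs(rng.normal(sigma, jitter["sigma"])))
        noise = ARNoiseParams(alpha, sigma, noise.period)
    return SensorErrorParams(
        KineticsParams(tau), base.cal_spec, CalibrationParams(tuple(a), tuple(b)), noise
    )


def generate_cohort(
    spec: CohortSpec, design: StudyDesign | None = None
) -> list[SyntheticSensor]:
    """Generate a cohort of synthetic sensors with known ground truth.

    Fully deterministic under the master seed: sensor i uses the seed
    sequence (seed, i+1), so regeneration is bit-identical.
    """
    design = design or StudyDesign()
    base = spec.base or reference_sensor_params()
    out = []
    for i in range(spec.n_sensors):
        ss = np.random.SeedSequence([spec.seed, i + 1])
        s_par, s_bg, s_cgm, s_ref = ss.spawn(4)
        truth = _draw_params(
            base, spec.jitter, np.random.default_rng(s_par), design.wear_days
        )
        bg = generate_bg(design.wear_days, seed=s_bg, settings=spec.bg_settings)
        cgm = simulate_cgm(bg, truth, design.cgm_period_min, seed=s_cgm)
        ref = sample_reference(bg, design, cv=spec.cv, seed=s_ref)
        record = SensorRecord(
            sensor_id=f"S{i + 1:03d}",
            cgm=cgm,
            reference=ref,
            session_days=design.session_start_days,
        )
        out.append(SyntheticSensor(record=record, truth=truth, bg=bg))
    return out
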