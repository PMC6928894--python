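"""Reference-profile reconstruction and CGM/reference alignment.

Laboratory reference blood-glucose samples (YSI-style) arrive every
~15 min inside discrete clinical sessions, while the sensor reports
every 5 min. To compare the two, each session's reference samples are
smoothed onto a 1-min grid by Tikhonov regularization: minimize

    (y - G u)' Sigma^-1 (y - G u)  +  gamma * || F2 u ||^2

where ``G`` samples the grid at the reference times, ``Sigma`` is the
diagonal reference-noise covariance with standard deviations
``cv * y_i`` (the analyzer error is modelled as white with a known
coefficient of variation, 2% by default), and ``F2`` is the
second-difference operator. Under the Bayesian reading — second
differences of the unknown profile are white noise of unknown variance
— the smoothing parameter ``gamma`` is tuned by maximizing the marginal
likelihood of the session data over a log-spaced grid.

Reconstruction is unreliable across gaps in the reference series, so
intervals between consecutive reference samples more than 20 min apart
are excluded, and CGM samples are paired only with covered grid points
at most 30 s away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.linalg import cho_solve_banded, cholesky_banded

from .error_model import GlucoseTrace

__all__ = [
    "ReferenceSamples",
    "SmoothProfile",
    "MatchedPairs",
    "mask_gaps",
    "smooth_reference",
    "match_cgm",
]

#: log10-spaced default search grid for the smoothing parameter.
DEFAULT_GAMMA_GRID = np.logspace(-4.0, 8.0, 61)


@dataclass
class ReferenceSamples:
    """Sparse reference BG samples with an assumed measurement
    coefficient of variation (default 2%)."""

    times: np.ndarray
    values: np.ndarray
    cv: float = 0.02

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape != self.times.shape:
            raise ValueError("times and values must have matching shapes")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite and positive")
        if not 0.0 < self.cv < 0.5:
            raise ValueError("cv must lie in (0, 0.5)")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SmoothProfile:
    """Reconstructed quasi-continuous BG profile on a 1-min grid.

    ``grid_times`` is evenly spaced at 1 min within each covered
    interval (one per smoothed session); ``excluded_intervals`` are open
    intervals where reconstruction is unreliable (reference gaps longer
    than 20 min).
    """

    grid_times: np.ndarray
    values: np.ndarray
    excluded_intervals: list[tuple[float, float]] = field(default_factory=list)
    gammas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape != self.grid_times.shape:
            raise ValueError("grid_times and values must have matching shapes")

    def __len__(self) -> int:
        return self.grid_times.size

    def contiguous_runs(self, step: float = 1.0, tol: float = 1e-6):
        """Yield slices over maximal runs with the declared grid step."""
        if not len(self):
            return
        breaks = np.flatnonzero(np.abs(np.diff(self.grid_times) - step) > tol) + 1
        edges = [0, *breaks.tolist(), len(self)]
        for a, b in zip(edges[:-1], edges[1:]):
            yield slice(a, b)


@dataclass
class MatchedPairs:
    """Aligned (reference BG, CGM) pairs on which identification runs.

    ``segment_ids`` label maximal runs of consecutive retained CGM
    samples; ``grid_index`` maps each pair onto the reference grid of
    ``profile`` so that model predictions can be formed by convolving
    the 1-min reference per segment.
    """

    times: np.ndarray
    reference: np.ndarray
    cgm: np.ndarray
    segment_ids: np.ndarray
    grid_index: np.ndarray
    profile: SmoothProfile | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        self.cgm = np.asarray(self.cgm, dtype=float).ravel()
        self.segment_ids = np.asarray(self.segment_ids, dtype=int).ravel()
        self.grid_index = np.asarray(self.grid_index, dtype=int).ravel()
        n = self.times.size
        for arr in (self.reference, self.cgm, self.segment_ids, self.grid_index):
            if arr.size != n:
                raise ValueError("all MatchedPairs fields must have equal length")

    @property
    def n(self) -> int:
        return self.times.size

    def segment_slices(self):
        if not self.n:
            return
        breaks = np.flatnonzero(np.diff(self.segment_ids) != 0) + 1
        edges = [0, *breaks.tolist(), self.n]
        for a, b in zip(edges[:-1], edges[1:]):
            yield slice(a, b)


def mask_gaps(
    samples: ReferenceSamples, max_gap: float = 20.0
) -> list[tuple[float, float]]:
    """Open intervals between consecutive reference samples spaced more
    than ``max_gap`` minutes apart."""
    t = samples.times
    if t.size < 2:
        return []
    gaps = np.diff(t)
    idx = np.flatnonzero(gaps > max_gap)
    return [(float(t[i]), float(t[i + 1])) for i in idx]


def _session_penalty_bands(m: int) -> np.ndarray:
    """Upper-banded storage of F2' F2 (pentadiagonal, bandwidth 2)."""
    e = np.ones(m - 2)
    f2 = sparse.diags([e, -2.0 * e, e], offsets=[0, 1, 2], shape=(m - 2, m))
    p = (f2.T @ f2).toarray()
    ab = np.zeros((3, m))
    ab[0, 2:] = np.diag(p, 2)
    ab[1, 1:] = np.diag(p, 1)
    ab[2, :] = np.diag(p)
    return ab


def _smooth_session(
    ts: np.ndarray,
    ys: np.ndarray,
    cv: float,
    gamma,
    gamma_grid: np.ndarray,
    criterion: str,
):
    """Smooth one session; returns (grid, values, chosen gamma)."""
    first = ts[0]
    m = int(np.floor(ts[-1] - first + 1e-9)) + 1
    grid = first + np.arange(m, dtype=float)
    cols = np.clip(np.rint(ts - first).astype(int), 0, m - 1)
    w = 1.0 / (cv * ys) ** 2
    diag_w = np.zeros(m)
    np.add.at(diag_w, cols, w)
    rhs = np.zeros(m)
    np.add.at(rhs, cols, w * ys)
    p_ab = _session_penalty_bands(m)

    def solve(g: float):
        ab = g * p_ab
        ab[2] += diag_w
        try:
            c = cholesky_banded(ab, lower=False)
        except np.linalg.LinAlgError as err:  # pragma: no cover - degenerate
            raise np.linalg.LinAlgError("singular smoothing system") from err
        u = cho_solve_banded((c, False), rhs)
        logdet = 2.0 * np.sum(np.log(c[-1]))
        resid = ys - u[cols]
        wrss = float(np.sum(w * resid**2))
        rough = float(np.sum(np.diff(u, 2) ** 2))
        return u, logdet, wrss, rough

    if gamma is not None:
        u, *_ = solve(float(gamma))
        return grid, u, float(gamma)

    best = None
    for g in gamma_grid:
        u, logdet, wrss, rough = solve(g)
        if criterion == "ml":
            # -2 log marginal likelihood up to a gamma-independent constant
            score = -(m - 2) * np.log(g) + logdet + wrss + g * rough
        elif criterion == "discrepancy":
            score = abs(wrss - ys.size)
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best is None or score < best[0]:
            best = (score, u, g)
    return grid, best[1], float(best[2])


def smooth_reference(
    samples: ReferenceSamples,
    session_bounds,
    gamma: float | None = None,
    gamma_grid: np.ndarray | None = None,
    criterion: str = "ml",
    max_gap: float = 20.0,
) -> SmoothProfile:
    """Reconstruct a 1-min BG profile from sparse reference samples.

    Each session (given as ``(start, end)`` minute intervals) is
    smoothed independently; sessions with fewer than 4 samples are
    skipped with a warning. ``gamma=None`` tunes the smoothing parameter
    per session by the marginal-likelihood criterion on ``gamma_grid``
    (default 61 log-spaced points spanning 1e-4..1e8); a fixed ``gamma``
    bypasses the search. ``criterion='discrepancy'`` selects the grid
    point whose weighted residual sum matches its expected value
    instead. No extrapolation is performed beyond a session's first and
    last sample.
    """
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    grids, vals, gammas = [], [], []
    for t0, t1 in session_bounds:
        mask = (samples.times >= t0) & (samples.times <= t1)
        ts, ys = samples.times[mask], samples.values[mask]
        if ts.size < 4:
            warnings.warn(
                f"session [{t0:g}, {t1:g}] min has {ts.size} reference "
                "samples (< 4); skipped",
                stacklevel=2,
            )
            continue
        grid, u, g = _smooth_session(ts, ys, samples.cv, gamma, gamma_grid, criterion)
        grids.append(grid)
        vals.append(u)
        gammas.append(g)
    if grids:
        grid_times = np.concatenate(grids)
        values = np.concatenate(vals)
    else:
        grid_times = np.empty(0)
        values = np.empty(0)
    return SmoothProfile(
        grid_times=grid_times,
        values=values,
        excluded_intervals=mask_gaps(samples, max_gap=max_gap),
        gammas=tuple(gammas),
    )


def match_cgm(
    profile: SmoothProfile,
    cgm: GlucoseTrace,
    max_dist_s: float = 30.0,
    cgm_period: float | None = None,
) -> MatchedPairs:
    """Pair each CGM sample with the nearest reference grid point.

    A pair is retained when the temporal distance is at most
    ``max_dist_s`` seconds and the grid point does not fall strictly
    inside an excluded (gap) interval. Ties between two equidistant grid
    points resolve to the earlier one. Segment ids label maximal runs of
    consecutive retained CGM samples (spacing ~ one CGM period).
    Deterministic and idempotent; an empty result is allowed.
    """
    grid = profile.grid_times
    empty = MatchedPairs(
        np.empty(0), np.empty(0), np.empty(0), np.empty(0, int), np.empty(0, int),
        profile=profile,
    )
    if grid.size == 0 or len(cgm) == 0:
        return empty
    pos = np.searchsorted(grid, cgm.times)
    left = np.clip(pos - 1, 0, grid.size - 1)
    right = np.clip(pos, 0, grid.size - 1)
    d_left = np.abs(cgm.times - grid[left])
    d_right = np.abs(grid[right] - cgm.times)
    use_left = d_left <= d_right  # tie -> earlier grid point
    gidx = np.where(use_left, left, right)
    dist = np.where(use_left, d_left, d_right)
    keep = dist <= max_dist_s / 60.0 + 1e-9
    gt = grid[gidx]
    for lo, hi in profile.excluded_intervals:
        keep &= ~((gt > lo + 1e-9) & (gt < hi - 1e-9))
    if not np.any(keep):
        return empty
    idx = np.flatnonzero(keep)
    times = cgm.times[idx]
    if cgm_period is None:
        cgm_period = float(np.median(np.diff(cgm.times))) if len(cgm) > 1 else 5.0
    new_seg = np.zeros(idx.size, dtype=int)
    if idx.size > 1:
        new_seg[1:] = (np.diff(times) > 1.5 * cgm_period).astype(int)
    return MatchedPairs(
        times=times,
        reference=profile.values[gidx[keep]],
        cgm=cgm.values[idx],
        segment_ids=np.cumsum(new_seg),
        grid_index=gidx[keep],
        profile=profile,
    )
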