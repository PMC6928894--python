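"""Cohort-level selection of the calibration error model.

For each sensor and each candidate pair of gain/offset function
families (5 x 5 = 25 candidates: polynomials of order 0-3 and an
exponential), the kinetics + calibration block is fitted by nonlinear
least squares, the residuals are whitened with a fitted AR(2) inverse
filter, and a BIC value is computed from the whitened residual sum of
squares. Candidates are then compared through the distribution, across
sensors, of their BIC difference from the time-invariant reference
model (poly0, poly0): the model with the lowest median difference wins,
and among candidates within a small equivalence margin the simplest one
(fewest calibration parameters) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .error_model import CALIBRATION_FAMILIES, CalibrationModelSpec
from .identification import compute_bic, fit_step1, whiten_residuals

__all__ = [
    "BicTable",
    "SelectionResult",
    "all_candidates",
    "reduced_candidates",
    "evaluate_candidates",
    "delta_bic",
    "select_optimal",
    "REFERENCE_LABEL",
]

REFERENCE_LABEL = "(poly0,poly0)"


def all_candidates() -> list[CalibrationModelSpec]:
    """The full 25-candidate grid."""
    return [
        CalibrationModelSpec(a, b)
        for a in CALIBRATION_FAMILIES
        for b in CALIBRATION_FAMILIES
    ]


def reduced_candidates() -> list[CalibrationModelSpec]:
    """A 9-candidate grid (polynomial orders 0-2 for both curves) for
    quick cohort studies."""
    fams = ("poly0", "poly1", "poly2")
    return [CalibrationModelSpec(a, b) for a in fams for b in fams]


@dataclass
class BicTable:
    """Per-sensor, per-candidate BIC values (whitened-RSS based)."""

    table: pd.DataFrame  # index: sensor ids, columns: candidate labels
    failures: list = field(default_factory=list)

    @property
    def candidates(self) -> list[str]:
        return list(self.table.columns)


def evaluate_candidates(
    cohort,
    candidates=None,
    sensor_ids=None,
    whiten_order: int = 2,
) -> BicTable:
    """Fit every candidate calibration model to every sensor's matched
    pairs and tabulate the BIC values.

    Per-cell convergence failures are recorded (as NaN cells) rather
    than raised. Deterministic given the data.
    """
    if candidates is None:
        candidates = all_candidates()
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if sensor_ids is None:
        sensor_ids = [f"S{i + 1:03d}" for i in range(len(cohort))]
    rows = {}
    failures = []
    for sid, pairs in zip(sensor_ids, cohort):
        row = {}
        for cand in candidates:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_step1(pairs, cand)
                    wr_segs, _ = whiten_residuals(fit.residuals, whiten_order)
                wr = np.concatenate(wr_segs) if wr_segs else np.empty(0)
                rss_w = float(wr @ wr)
                row[cand.label] = compute_bic(rss_w, wr.size, cand.n_params)
            except (ValueError, np.linalg.LinAlgError) as err:
                failures.append((sid, cand.label, str(err)))
                row[cand.label] = np.nan
        rows[sid] = row
    return BicTable(pd.DataFrame.from_dict(rows, orient="index"), failures)


def delta_bic(table: BicTable, reference: str = REFERENCE_LABEL) -> pd.DataFrame:
    """Per-candidate vector (over sensors) of BIC(candidate) -
    BIC(reference)."""
    if reference not in table.table.columns:
        raise ValueError(f"reference candidate {reference!r} not in table")
    return table.table.sub(table.table[reference], axis=0)


def _simplicity_key(label: str) -> tuple[int, int, int]:
    spec = CalibrationModelSpec.from_label(label)

    def order(fam: str) -> int:
        return 4 if fam == "exp" else int(fam[-1])

    return (spec.n_params, order(spec.a_family), order(spec.b_family))


@dataclass
class SelectionResult:
    """Selected candidate plus the ranking evidence."""

    selected: str
    spec: CalibrationModelSpec
    median_delta_bic: pd.Series
    contenders: list[str]  # candidates within the equivalence margin


def select_optimal(
    table: BicTable,
    reference: str = REFERENCE_LABEL,
    margin: float = 2.0,
) -> SelectionResult:
    """Select the candidate with the lowest median delta-BIC relative to
    the time-invariant reference model.

    Candidates whose medians lie within ``margin`` BIC units of the best
    are treated as equivalent and the one with the fewest calibration
    parameters wins (ties broken toward the lower-order gain family).
    """
    d = delta_bic(table, reference)
    med = d.median(axis=0, skipna=True)
    best = med.min()
    contenders = sorted(med.index[med <= best + margin], key=_simplicity_key)
    selected = contenders[0]
    return SelectionResult(
        selected=selected,
        spec=CalibrationModelSpec.from_label(selected),
        median_delta_bic=med.sort_values(),
        contenders=contenders,
    )
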