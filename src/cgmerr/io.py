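"""File formats: glucose-trace / reference CSVs and parameter JSON.

CSV dialect is fixed: comma separator, '.' decimal, UTF-8, mandatory
header; times are always minutes since sensor insertion as floats.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .error_model import (
    ARNoiseParams,
    CalibrationModelSpec,
    CalibrationParams,
    GlucoseTrace,
    KineticsParams,
    SensorErrorParams,
)
from .identification import FitResult, params_to_dict
from .smoothing import ReferenceSamples

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_reference_csv",
    "write_reference_csv",
    "params_to_json_dict",
    "params_from_json_dict",
    "read_params_json",
    "write_params_json",
    "fit_result_to_dict",
]


def write_trace_csv(trace: GlucoseTrace, path) -> None:
    pd.DataFrame(
        {
            "time_min": trace.times,
            "glucose_mg_dl": trace.values,
            "segment_id": trace.segment_ids,
        }
    ).to_csv(path, index=False)


def read_trace_csv(path) -> GlucoseTrace:
    df = pd.read_csv(path)
    return GlucoseTrace(
        df["time_min"].to_numpy(float),
        df["glucose_mg_dl"].to_numpy(float),
        df["segment_id"].to_numpy(int) if "segment_id" in df else None,
    )


def write_reference_csv(samples: ReferenceSamples, path) -> None:
    pd.DataFrame(
        {"time_min": samples.times, "glucose_mg_dl": samples.values}
    ).to_csv(path, index=False)


def read_reference_csv(path, cv: float = 0.02) -> ReferenceSamples:
    df = pd.read_csv(path)
    return ReferenceSamples(
        df["time_min"].to_numpy(float), df["glucose_mg_dl"].to_numpy(float), cv=cv
    )


def params_to_json_dict(params: SensorErrorParams) -> dict:
    d = {
        "tau_min": params.kinetics.tau,
        "cal_spec": {
            "a_family": params.cal_spec.a_family,
            "b_family": params.cal_spec.b_family,
        },
        "a_coeffs": list(params.cal.a_coeffs),
        "b_coeffs": list(params.cal.b_coeffs),
    }
    if params.noise is not None:
        d["ar_coeffs"] = [float(c) for c in params.noise.alpha]
        d["sigma_mg_dl"] = params.noise.sigma
        d["period_min"] = params.noise.period
    return d


def params_from_json_dict(d: dict) -> SensorErrorParams:
    noise = None
    if "ar_coeffs" in d:
        noise = ARNoiseParams(
            np.asarray(d["ar_coeffs"], float),
            float(d.get("sigma_mg_dl", 0.0)),
            float(d.get("period_min", 5.0)),
        )
    return SensorErrorParams(
        kinetics=KineticsParams(float(d["tau_min"])),
        cal_spec=CalibrationModelSpec(
            d["cal_spec"]["a_family"], d["cal_spec"]["b_family"]
        ),
        cal=CalibrationParams(tuple(d["a_coeffs"]), tuple(d["b_coeffs"])),
        noise=noise,
    )


def write_params_json(params: SensorErrorParams, path) -> None:
    Path(path).write_text(json.dumps(params_to_json_dict(params), indent=2) + "\n")


def read_params_json(path) -> SensorErrorParams:
    return params_from_json_dict(json.loads(Path(path).read_text()))


def fit_result_to_dict(fit: FitResult) -> dict:
    """JSON-serializable summary of a fit."""
    return {
        "method": fit.method,
        "params": params_to_json_dict(fit.params),
        "estimates": {k: float(v) for k, v in params_to_dict(fit).items()},
        "rss_raw": fit.rss_raw,
        "rss_whitened": fit.rss_whitened,
        "bic": None if fit.bic is None or not np.isfinite(fit.bic) else fit.bic,
        "n_used": fit.n_used,
        "converged": fit.converged,
        "se": fit.se,
        "cv_of_estimates": fit.cv_of_estimates,
    }
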