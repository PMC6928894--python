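import numpy as np
import pytest

from cgmerr.error_model import (
    CalibrationModelSpec,
    CalibrationParams,
    GlucoseTrace,
    KineticsParams,
    SensorErrorParams,
)
from cgmerr.recovery import true_reference_pairs
from cgmerr.synthetic_data import (
    CohortSpec,
    StudyDesign,
    generate_cohort,
    reference_sensor_params,
)


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture(scope="session")
def median_params() -> SensorErrorParams:
    return reference_sensor_params()


@pytest.fixture(scope="session")
def noisy_sensor(design):
    """One synthetic sensor at the population medians, with its
    true-reference matched pairs."""
    sensor = generate_cohort(CohortSpec(n_sensors=1, seed=5), design)[0]
    pairs = true_reference_pairs(sensor.bg, sensor.record.cgm, design)
    return sensor, pairs


@pytest.fixture(scope="session")
def noiseless_sensor(design, median_params):
    """A noiseless sensor with a genuinely quadratic gain drift (so all
    generating parameters are identifiable) and its matched pairs."""
    from dataclasses import replace

    from cgmerr.error_model import ARNoiseParams

    truth = SensorErrorParams(
        kinetics=KineticsParams(5.0),
        cal_spec=CalibrationModelSpec("poly2", "poly0"),
        cal=CalibrationParams((0.95, 0.02, -0.002), (7.3,)),
        noise=ARNoiseParams(np.array([1.30, -0.42]), 0.0, 5.0),
    )
    spec = CohortSpec(n_sensors=1, base=truth, seed=9)
    sensor = generate_cohort(spec, design)[0]
    pairs = true_reference_pairs(sensor.bg, sensor.record.cgm, design)
    return sensor, pairs


def constant_trace(value: float, n: int = 200, step: float = 1.0) -> GlucoseTrace:
    return GlucoseTrace(np.arange(n) * step, np.full(n, float(value)))
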