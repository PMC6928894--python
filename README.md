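# cgmerr

Error model of factory-calibrated continuous glucose monitoring (CGM)
sensors: forward simulation and parameter identification.

## The problem

Factory-calibrated CGM sensors (10-day wear, ~5-min sampling, no
in-vivo recalibration) measure interstitial glucose (IG), not blood
glucose (BG), and their output accumulates three distinct error
components over the sensor lifetime:

1. **Plasma-to-interstitium kinetics** — first-order diffusion with
   impulse response `h(t) = (1/τ) e^(−t/τ)`, so `IG = h ⊗ BG`: the
   sensed signal lags BG by a time constant τ of a few minutes.
2. **Calibration error** — a slowly varying gain/offset distortion
   `IGs(t) = a(t)·IG(t) + b(t)`, with `a(t)` and `b(t)` drawn from
   candidate families (polynomials of order 0–3 in time-since-insertion,
   or an exponential), 25 candidate pairs in all.
3. **Measurement noise** — additive autoregressive noise at the CGM
   period T, `v(t) = Σ_k α_k v(t−kT) + w(t)`, `w` white with SD σ:
   `CGM(t) = IGs(t) + v(t)`.

`cgmerr` implements this model both as a **simulator** (generate
realistic synthetic CGM traces from a BG profile with known error
parameters) and as an **identification engine**: given CGM readings
matched to laboratory reference BG within clinical sessions, estimate
θ = {τ, calibration coefficients} and the noise parameters {α, σ} by

- the classical **two-step** procedure: nonlinear least squares for θ
  (residuals whitened by an inverse fitted AR(2) filter before BIC
  model selection), then a forward–backward AR fit to the residuals;
- a **single-step** procedure minimizing the whitened residual sum
  `Σ_j [r_j(θ) − Σ_k α_k r_{j−k}(θ)]²` jointly over (θ, α) under the AR
  stationarity constraint.

Candidate calibration models are compared across a sensor cohort by the
distribution of per-sensor BIC differences from the time-invariant
(poly0, poly0) model. Because the clinical dataset such models are
built on is proprietary, the package ships a synthetic-data module that
reproduces the study design (three 12-h in-clinic sessions on days
2/4/10 with 15-min reference sampling at 2% CV) so every estimator can
be validated by parameter recovery against known ground truth.

Intended users: researchers building in-silico diabetes-therapy
simulators who need realistic CGM error generation, and sensor-accuracy
analysts identifying error models from clinical studies.

## Worked example

Simulate one 10-day sensor at the population-median parameters
(τ = 3.78 min, a(t) = 0.95 + 0.004 t − 0.000 t², b₀ = 6.35 mg/dL,
α = (1.30, −0.42), σ = 3.19 mg/dL) and identify it with both
procedures, using the true BG as forcing input:

```python
from cgmerr import CohortSpec, StudyDesign, generate_cohort
from cgmerr import two_step_identify, single_step_identify
from cgmerr.recovery import true_reference_pairs
from cgmerr.identification import params_to_dict

design = StudyDesign()                      # 10-day wear, sessions on days 2/4/10
sensor = generate_cohort(CohortSpec(n_sensors=1, seed=5), design)[0]
pairs = true_reference_pairs(sensor.bg, sensor.record.cgm, design)
two = two_step_identify(pairs, sensor.truth.cal_spec)
single = single_step_identify(pairs, sensor.truth.cal_spec, init=two)
```

prints, per procedure:

```
two-step    tau=3.34 min  a0=0.897  b0=19.66 mg/dL  alpha=(1.31,-0.46)  sigma=3.20 mg/dL  whitened RSS=4362
single-step tau=2.83 min  a0=0.897  b0=19.88 mg/dL  alpha=(1.30,-0.46)  sigma=3.20 mg/dL  whitened RSS=4358
```

The noise block (α, σ) is recovered tightly on a single sensor, and the
single-step whitened RSS is never worse than the two-step one (it is
initialized at the two-step solution). The per-sensor gain/offset
estimates scatter — a₀ and b₀ are extrapolations to insertion time from
data observed only on days 2, 4 and 10 — but they are unbiased: across
a 40-sensor cohort (`run_recovery_study(n_sensors=40, seed=1)`, ~5 s)
the single-step cohort medians come back as

```
tau 3.56 min   a0 0.962   b0 5.77 mg/dL   alpha (1.293, -0.419)   sigma 3.15 mg/dL
```

against generating values τ = 3.78, a₀ = 0.95, b₀ = 6.35,
α = (1.30, −0.42), σ = 3.19.

A CLI wraps the pipeline for shell use:

```bash
cgmerr simulate -n 5 --seed 1 --out-dir data/        # cohort CSVs + truth JSON
cgmerr identify --data-dir data/ --out-dir fits/ --method both
cgmerr select-model --data-dir data/ --out-dir sel/  # 25-candidate BIC comparison
cgmerr recover --n-sensors 40 --seed 1 --out-dir rec/
```

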