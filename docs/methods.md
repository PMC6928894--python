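# Methods

This note documents the model, the numerical and design choices, and
what the synthetic-data studies do and do not demonstrate.

## Model

A CGM reading at time t (minutes since sensor insertion) is modelled as
three blocks in series applied to the blood-glucose profile BG(t):

1. **Kinetics.** `IG(t) = (h ⊗ BG)(t)` with
   `h(t) = (1/τ) e^(−t/τ)`, τ ≥ 0 in minutes. This is the reduced form
   of a two-compartment plasma/interstitium exchange under the
   steady-state balance assumption; h integrates to one, so constant BG
   passes through unchanged. τ is treated as specific to the
   subject–sensor coupling, not the subject alone.
2. **Calibration error.** `IGs(t) = a(t)·IG(t) + b(t)`. Each of a and b
   belongs to one of five families: polynomials of order m = 0..3 in
   time since insertion, or a three-parameter exponential. The
   polynomial argument is time in **days**, so the k-th coefficient
   carries days^−k units. The exponential is parametrized by initial
   value, final value and time constant (days):
   `f(t) = p₁ + (p₀ − p₁) e^(−t/p₂)` — the unique curve with exactly
   those three named parameters.
3. **Noise.** `CGM(t) = IGs(t) + v(t)` with
   `v(t) = Σ_{k=1..q} α_k v(t−kT) + w(t)` at the CGM period T (5 min by
   default), w zero-mean Gaussian white noise of SD σ. Gaussianity is a
   modelling choice (only "zero-mean white" is structurally required);
   it is what least-squares identification implicitly assumes.
   Stationarity — all roots of `z^q − α₁ z^{q−1} − … − α_q` strictly
   inside the unit circle — is enforced at construction.

The receiver clips readings to the display range [40, 400] mg/dL;
clipped samples are flagged by the simulator and removed by
preprocessing, mirroring the saturation-removal rule applied to real
traces.

## Discretization

The kinetics block is discretized per uniformly sampled segment with
the exact zero-order-hold recursion

    IG[k] = φ·IG[k−1] + (1−φ)·BG[k],   φ = exp(−Δ/τ),

which is unconditionally stable and exact for piecewise-constant input,
with steady-state initial condition IG[0] = BG[0] at the start of each
segment. τ = 0 is the identity. The steady-state initial condition is
the natural counterpart of the model's steady-state balance assumption;
its practical consequence is a small transient at the start of each
clinical session (decaying with τ), which is why even noise-free fits
have a tiny nonzero residual sum.

## Reference smoothing

Reference BG samples arrive every ~15 min inside sessions with analyzer
noise of known coefficient of variation (2% default). Each session is
reconstructed on a 1-min grid u by Tikhonov regularization,

    min_u (y − Gu)ᵀ Σ⁻¹ (y − Gu) + γ uᵀF₂ᵀF₂u,

Σ = diag((cv·y_i)²) (measured values stand in for the unknown truth),
F₂ the second-difference operator. Under the Bayesian reading (second
differences of u are white with unknown variance, improper prior on the
linear component) γ is chosen by maximizing the marginal likelihood

    −2 log L(γ) = −(m−2)·ln γ + ln det H(γ) + J(û(γ)) + const,

H(γ) = GᵀΣ⁻¹G + γF₂ᵀF₂, J the penalized objective at the minimizer,
searched on a 61-point log grid spanning 10⁻⁴..10⁸. H is pentadiagonal,
so solves and log-determinants use banded Cholesky factorizations
(O(m) per γ). A discrepancy-based fallback (weighted residual sum
matched to its expectation) is available behind `criterion=
"discrepancy"`. Sessions are smoothed independently — they are days
apart, and the penalty is meaningless across such gaps — and no
extrapolation is performed beyond a session's first and last sample.
Linear profiles lie in the penalty null space and are reproduced
exactly (to solver conditioning, ~10⁻³ mg/dL at small γ); as γ → ∞ the
reconstruction tends to the weighted least-squares line (the practical
limit is conditioning-bound at γ ≈ 10¹⁰, agreeing with a direct
weighted regression to ~0.05 mg/dL).

Gaps: when consecutive reference samples are more than 20 min apart,
the open interval between them is excluded and CGM samples inside it
are dropped. Matching pairs each CGM sample with the nearest grid point
within 30 s; an exact 15-s tie resolves to the earlier point
(documented, arbitrary). Matched pairs are partitioned into maximal
runs of consecutive CGM samples; all lagged operations below respect
these segment boundaries.

## Identification

**Two-step.** Step 1 estimates θ = {τ, calibration coefficients} by
nonlinear least squares on raw residuals, with τ bounded in [0, 60] min
(estimates near 0 occur and must be feasible; 60 min is a generous
physiological ceiling) and all variables scaled to O(1) (τ/10,
calibration time in days). The optimizer is a trust-region-reflective
least-squares solver with first-order tolerance 10⁻⁸; initialization
τ = 7 min, a ≡ 1, b ≡ 0. Because the residuals are autocorrelated, BIC
for calibration-model selection is computed on whitened residuals: an
AR(2) is fitted to the raw residuals (order 2 fixed, following the
standing result that CGM noise is well described at second order) and
its inverse filter applied per segment, dropping the first two samples
of each segment. BIC = n·ln(RSS/n) + (N_p+1)·ln(n), where n counts the
whitened residuals actually summed and the +1 accounts for τ. Step 2
fits AR(q) to the raw residuals by forward–backward (modified
covariance) least squares, pooling segments without cross-segment lag
products; σ̂ is the RMS of one-step forward prediction errors; q is
selected by BIC over q = 1..10 (with q+1 parameters counting σ).
Nonstationary AR estimates (rare) are projected radially to just inside
the unit circle.

**Single-step.** All parameters (θ, α) are estimated jointly by
minimizing the whitened residual sum of squares, the first q pairs of
each segment excluded, subject to stationarity: for q = 2 the open
triangle α₁+α₂ < 1, α₂−α₁ < 1, |α₂| < 1 shrunk by a margin of 10⁻³ (as
linear constraints), a root-magnitude constraint otherwise. The solver
is a sequential-quadratic-programming local optimizer. θ and α are
initialized from the sensor's own two-step solution (run internally
when not supplied). Because the whitening filter and the step-2 AR fit
use the same estimator, the single-step objective at its initialization
equals the two-step whitened RSS exactly; if the constrained optimizer
fails to improve on it, the initialization is returned (flagged not
converged), so the single-step whitened RSS is never worse by
construction. σ̂ is the sample SD of the whitened residuals at the
optimum.

**Uncertainty.** Approximate standard errors use the Gauss–Markov
formula σ̂²(JᵀJ)⁻¹ on the whitened Jacobian at the optimum (the AR
design matrix for two-step noise coefficients); the per-parameter CV of
the estimation error is se/|estimate|. This is a local linearization
and is optimistic when τ sits on its bound.

**Model selection.** Candidates are ranked by the median, across
sensors, of BIC(candidate) − BIC(poly0, poly0). "Lowest distribution"
is operationalized as lowest median; candidates within 2 BIC units of
the best are treated as equivalent and the one with fewest calibration
parameters wins (ties toward the lower-order gain family, the
exponential ranking after poly3).

## Synthetic data

BG profiles are sums of meal-excursion kernels — unit-peak
logistic-rise × exponential-decay bumps (rise 30–60 min, decay constant
60–120 min, amplitude 60–140 mg/dL, three meals/day at randomized
times) — over a constant baseline in 110–140 mg/dL, with occasional
nocturnal dips of 40–55 mg/dL. The construction is smooth (so the
smoother's roughness prior is appropriate) and confined to
[50, 350] mg/dL, so receiver saturation arises only through gain drift
or noise. The clinical design defaults match the study the model
targets: 10-day wear, three 12-h sessions starting at the beginning of
days 2, 4 and 10, reference samples every 15 min within sessions
(inclusive start, exclusive end: 48 per session) with 2% CV Gaussian
noise, CGM every 5 min. Everything is deterministic under a master
seed via per-sensor seed sequences.

What the synthetic BG does **not** emulate: real meal-response
asymmetries and overnight drift, sensor dropouts, pressure-induced
attenuations, or any BG dynamics beyond kernel sums. Recovery results
therefore validate the identification machinery under the model's own
assumptions; they do not certify performance on real traces.

### Parameter populations

- **Recovery studies** fix every generating parameter at the
  population medians (τ = 3.78 min, a = (0.95, 0.004, 0.000) days^−k,
  b₀ = 6.35 mg/dL, α = (1.30, −0.42), σ = 3.19 mg/dL at T = 5 min), so
  cohort medians of the estimates can be compared directly with the
  generating values. Measured at 40 sensors: single-step medians within
  0.25 min (τ), 0.012 (a₀), 0.6 mg/dL (b₀), 0.01 (α) and 0.04 mg/dL
  (σ) of truth.
- **Heterogeneous cohorts** optionally draw coefficients with normal
  jitter whose SDs derive from the published interquartile ranges
  (IQR/1.349): a₀ 0.126, a₁ 0.049, a₂ 0.0045, b₀ 6.03; τ log-normal.
  Independently drawn coefficients can compose into gain curves that
  collapse or explode over 10 days (the real coefficients are
  correlated), so draws are rejected until the gain stays within
  (0.3, 2.5) and |offset| < 25 mg/dL over the wear period.
- **Model-selection studies** need the generating family's
  highest-order component to be identifiable: with the median
  population the quadratic gain coefficient is zero and the
  "(poly2, poly0)" generator is observationally identical to
  "(poly1, poly0)". The selection-study population therefore draws the
  top coefficient with random sign and magnitude uniform in an
  identifiable range (a₂ ∈ 0.005–0.012 days⁻², within the upper spread
  individual sensors exhibit), the remaining coefficients at the
  population SDs. At 20 sensors/cohort this recovers the generating
  family reliably; with median-scale |a₂| ≲ 0.003 the BIC criterion
  correctly prefers the first-order model — a statement about the data,
  not a defect of the selector.

## Problem sizes and numerical details

Studies default to 40 sensors (recovery) and 5 cohorts × 20 sensors
per generating family on a reduced 9-candidate grid {poly0,1,2}²
(selection), sizes at which cohort medians are stable while a full
study runs in seconds to a couple of minutes on one core. The AR-order
study uses 100 replicates of n = 5000. Degenerate inputs are handled
explicitly: sessions with < 4 reference samples are skipped, segments
shorter than the AR order contribute no whitened residuals, zero RSS
maps BIC to −∞ with a warning, and all-saturated traces come back
empty.

## Known limitations

- a₀ and b₀ are extrapolations to insertion time from sessions on days
  2/4/10; their per-sensor estimates scatter widely (and trade off
  against a₁, a₂) even though cohort medians are unbiased.
- The two-step τ estimate has a spread of ±2 min under realistic noise;
  the single-step procedure tightens the distribution but both are
  exact only in the noise-free limit.
- The marginal-likelihood γ search is a grid search; γ between grid
  points is not refined (the BIC-scale effect is negligible).
- CV-of-estimate figures rely on local linearization and a correctly
  specified model; they are indicative, not calibrated confidence
  statements.
- The automated reference-outlier flag is a stand-in for manual visual
  inspection, is off by default, and flags the neighbours of a large
  spike along with the spike itself.
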