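# Methods

This note documents the models, numerical choices and open design decisions
behind `tobramipd`, and what the synthetic cohort does and does not show.

## Kinetic model

The drug follows linear two-compartment kinetics with zero-order infusion
input into the central compartment. With micro-constants K<sub>e</sub>
(elimination from central), k<sub>12</sub>, k<sub>21</sub>
(intercompartmental) and central volume V<sub>1</sub>, the central
concentration after a bolus is bi-exponential in the hybrid constants α ≥ β,
the roots of s² − (K<sub>e</sub>+k<sub>12</sub>+k<sub>21</sub>)s +
K<sub>e</sub>k<sub>21</sub>. The infusion response is the running integral
of the bolus kernel; a finite infusion is the difference of two shifted
"infusion-on" responses, and multi-dose profiles are superpositions over
events (the model is linear, which the test suite exploits:
dose-proportionality and event-superposition hold to ~1e-12 relative).

Numerical choices:

- β is computed as (K<sub>e</sub>k<sub>21</sub>)/α rather than via the
  quadratic formula's subtraction, avoiding cancellation when β ≪ α.
- (1 − e^(−rt))/r is evaluated with `expm1` and switches to its r → 0 limit
  (= t), which covers the one-compartment case (k<sub>12</sub> = k<sub>21</sub> = 0,
  where β = 0 exactly).
- The repeated-eigenvalue case α = β (e.g. K<sub>e</sub> = k<sub>21</sub>,
  k<sub>12</sub> = 0) is handled by the analytic limit kernel
  e^(−αt)(1 + (k<sub>21</sub>−α)t); the branch triggers at
  |α−β|/α < 1e-9.
- Closed form agrees with high-accuracy ODE integration (`solve_ivp`,
  rtol 1e-11, integrated piecewise between input discontinuities) to
  better than 1e-6 relative on 100 random parameter sets.

Covariate links: V<sub>1</sub> = V<sub>s</sub>·BW and
K<sub>e</sub> = K<sub>I</sub> + K<sub>S</sub>·CL<sub>CR</sub>, with
CL<sub>CR</sub> from Cockcroft–Gault. Creatinine is stored in µmol/L
(French laboratory convention) and divided by 88.4 inside the equation; no
upper cap is applied to the computed clearance. Time is in hours with each
course's clock starting at the first infusion; peripheral amounts start at
zero (courses are weeks apart, so no carry-over).

## Standardized exposures

Because real infusion durations (observed 20–60 min) and peak sampling
times (4–69 min after infusion end) deviate from the nominal schedule,
target attainment is judged on model-standardized quantities:

- **Cmax_mod** — concentration at t = 1.0 h after infusion start for a
  standardized 0.5-h infusion (i.e. 30 min after the end of a 30-min
  infusion);
- **Cmin_24** — concentration 24 h after infusion start, immediately before
  the next dose.

Both are evaluated at steady state by explicit 7-dose superposition.
Seven doses put accumulation above 99% of the asymptote for the slowest
plausible terminal slope in the prior, and explicit superposition avoids
the repeated-eigenvalue corner cases of closed-form accumulation factors.
With troughs below 0.5 mg/L the accumulation is minor anyway (first-dose vs
steady-state differences < 2% in practice).

## Observation model and BLQ handling

Measurement error is Gaussian with SD(C) = c₀ + c₁·C evaluated at the
model-predicted concentration. Defaults c₀ = 0.1 mg/L (half the
quantification limit, an additive floor) and c₁ = 0.04 (the assay's
reported < 4% CV bound); the clinical assay's exact polynomial is
site-specific, so both are configurable. Concentrations strictly below the
0.2 mg/L LLOQ are replaced by 0.1 mg/L (half-LLOQ substitution) and flagged;
a value of exactly 0.2 is quantifiable and kept. A censored (M3-type)
likelihood is deliberately not used — the substitution rule mirrors the
clinical workflow being modeled.

## Discrete Bayesian estimation

The prior is a finite set of support points on
(V<sub>s</sub>, K<sub>I</sub>, K<sub>S</sub>, k<sub>12</sub>, k<sub>21</sub>)
with probability weights. The posterior multiplies each prior weight by the
Gaussian likelihood of the course's observations — computed at the recorded
sampling times with the recorded infusion durations — and renormalizes.
The log-likelihoods are shifted by their maximum before exponentiation, so
adding any constant to all log-likelihoods leaves the weights bit-identical;
a non-finite prediction maps to −∞ likelihood (the point drops out) rather
than an error.

Point estimates: the reported V<sub>1</sub>, K<sub>e</sub> and clearance
(K<sub>e</sub>·V<sub>1</sub>) come from the posterior-mean population
parameters mapped through the covariate model. Per-observation *predicted
concentrations*, however, come from the maximum-posterior-weight support
point (the Bayesian individual fit). Predicting from mean parameters would
systematically misstate the trough — the trough depends exponentially on
K<sub>e</sub>, so the prediction of the mean is not the mean of the
predictions, and the discrepancy can exceed the 20% fit-quality trigger on
perfectly healthy fits.

**Default synthetic prior.** The published pediatric population model's
support points are not public, so the default prior is an explicitly
labeled synthetic construction: 2,000 scrambled-Sobol points (seeded,
reproducible bit-for-bit), log-uniform over V<sub>s</sub> ∈ [0.15, 0.55] L/kg,
K<sub>I</sub> ∈ [0.003, 0.03] h⁻¹, K<sub>S</sub> ∈ [0.0015, 0.005] h⁻¹ per
mL/min, k<sub>12</sub>, k<sub>21</sub> ∈ [0.05, 4] h⁻¹, equal weights.
These ranges are deliberately wide (robust estimation), which makes the
prior far more diffuse than a fitted population model — see Limitations.
Site priors load from a strict-schema JSON file and are renormalized on
load (with a warning beyond 1e-6).

**Hybrid fit.** Triggered when > 50% of posterior mass sits on boundary
points or the fit's median absolute percentage error exceeds 20%. A point
counts as "boundary" when within 1% (log-scale fraction of the range) of
any bound in any dimension: with five dimensions the prior's own boundary
mass is then ≈ 1 − 0.98⁵ ≈ 10%, so the 50% trigger detects genuine
edge-piling rather than mere posterior diffuseness (a looser 5% definition
was rejected: it labels ~41% of the prior itself as boundary and fires on
healthy diffuse posteriors). The refit doubles each bound outward
(lo/2, hi×2), appends a 500-point quasi-random auxiliary grid carrying half
the total prior mass, and reruns the update. The trigger thresholds and
expansion constants are this package's own conservative choices — the
commercial tool's internals are proprietary.

## Dose design

For target T, the continuous dose minimizes the posterior-expected squared
deviation of Cmax_mod from T. By linearity each point contributes a unit
response a<sub>i</sub>, giving the closed form
D\* = T·Σwₐaᵢ / Σwᵢaᵢ² — the "multiple-model" dosage-design optimum. A
posterior-mean-parameter alternative exists conceptually but is not the
default and is not used anywhere in the shipped analyses. Doses are rounded
**up** to the 25-mg grid (under-dosing was the problem the service
corrected; exact multiples are unchanged), and predictions at the grid dose
are reported with warnings when the expected 24-h trough reaches 0.5 mg/L
(the interval is fixed at 24 h; extension is out of scope) or when rounding
pushes the predicted peak outside [30, 40] mg/L.

Note an intrinsic property of the squared-error optimum: the predicted peak
at D\* is T/(1 + cv²), where cv is the posterior coefficient of variation
of the unit response — always slightly *below* T for an uncertain
posterior. With an informative prior (cv of a few percent) the upward grid
rounding absorbs this; with the wide synthetic prior it can leave the
predicted peak marginally below 30 mg/L (see Limitations).

## Cohort analytics

- Attainment bins on the standardized peak: below (< 30), in-range (the
  closed interval [30, 40]), above (> 40); the trough criterion is strict
  (< 0.5 mg/L). Edge conventions are explicit because published tables
  rarely state them.
- Expected attainment after adjustment = proportion of accepted doses whose
  predicted Cmax_mod lies in [30, 40].
- Dose changes are exact comparisons (unchanged / increase / decrease),
  stratified by estimated-peak bin; missing accepted doses are "not
  adjusted" and excluded from paired tests.
- AKI marker: serum-creatinine rise ≥ 50% from baseline (inclusive
  threshold); a missing end-of-therapy creatinine makes the course
  unevaluable — never imputed.
- Wilcoxon signed-rank (two-sided): zero differences dropped, exact null
  for n ≤ 25 without ties, otherwise normal approximation with tie and
  continuity corrections (delegated to `scipy.stats.wilcoxon`; the test
  suite cross-checks against exhaustive sign-pattern enumeration for all
  n ≤ 10).

## Synthetic cohort

The generator draws patients to the study's demographic moments: weight
~ N(57.5, 12.3²) kg truncated to [35, 80] (symmetric about the mean so
truncation leaves it unbiased; CF adults are characteristically
underweight), age ~ N(32.4, 10²) y in [18, 65], 69% women, target
clearance ~ N(112.7, 28.4²) mL/min in [30, 200] with serum creatinine
back-solved through the Cockcroft–Gault inverse so the derived clearance
equals the draw exactly. Physician initial doses are N(9.16, 1.42²) mg/kg
× weight rounded to the *nearest* 25 mg (nearest, not ceiling: prescribers
round to the closest ampoule size, and ceiling would bias the cohort mean
up by ~0.22 mg/kg). Fourteen once-daily doses; one TDM occasion on day 3
or 4 with jittered infusion duration (N(35.9, 7.4²) min in [20, 60]) and
peak delay (N(32.1, 8.9²) min in [4, 69] — the observed extremes); trough
24 h after that infusion's start. Observations carry proportional noise
(CV 4%) and are BLQ-flagged below 0.2 mg/L. End-of-therapy creatinine is
log-symmetric (SD 0.12, calibrated so the cohort clearance-change SD is
≈ 18 mL/min) with a 1.3% AKI branch (uniform 50–100% rise) and an 8/77
missing fraction. True parameters are drawn from the analysis prior;
repeat-course patients (17 of 61 by default, giving 78 courses) keep their
kinetics and redraw creatinine. Everything is reproducible from a single
seed.

**Mismatch mode** multiplies the true V<sub>s</sub> by a configurable
factor. The shipped end-to-end experiment uses a factor of 1.2,
calibrated against the generator itself so that well over 60% of courses
fall below the 30 mg/L target at ~9.2 mg/kg dosing and so that part of the
cohort lies genuinely outside the prior's V<sub>s</sub> range, exercising
the hybrid-fit path on a minority of courses.

What the generator does *not* emulate: physician acceptance behavior,
interoccasion variability, assay-specific error structure beyond the
linear SD model, within-course renal drift (creatinine moves only between
start and end), and any dependence of nephrotoxicity on exposure — the
creatinine stream is independent of dose by construction, which is exactly
what makes the "no induced renal change" check meaningful.

## Limitations

- The default prior is synthetic. Its wide log-uniform ranges make
  posteriors from a two-sample design substantially more diffuse than a
  fitted population model would: deep-distribution phenotypes
  (k<sub>12</sub> large, k<sub>21</sub> small) can fit a peak + trough pair
  while disagreeing on the steady-state standardized peak by tens of
  percent. Consequences: recommended doses for large-volume virtual
  patients can far exceed the clinical 400–700 mg range, and the predicted
  peak at the 30 mg/L-target dose sits marginally below 30 for
  high-uncertainty courses (the T/(1+cv²) effect above), which makes the
  cohort-level "expected attainment > 80%" figure a knife-edge quantity
  (≈ 73–86% across seeds) rather than the comfortably high value a
  clinical prior yields.
- Parameter-recovery results with truth drawn from the analysis prior are
  an internal-consistency check, not evidence about real patients.
- One TDM occasion per course; no interval optimization, loading doses,
  MIC-individualized or AUC-based targets, and no renal-replacement or
  pediatric settings.
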