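# Methods

`bcscreen` simulates the natural history of breast cancer in a population of
women, superimposes mammography screening programs, and analyzes how
body-mass index (BMI) shapes the balance between screen-detected and
interval-detected (symptomatic between screens) cancers.  This note records
the model, its parameters, the numerical and design choices that were
genuinely open, and what the synthetic study populations do and do not
represent.

## Natural-history model

**Tumor onset.** Onset ages follow a two-stage clonal-expansion (MVK)
survival function

    F_T(t) = [ (B − A) e^{Bt} / (B e^{(B−A)t} − A) ]^δ ,

with the identifiable triple reparameterized from the four Poisson event
rates (cell division α̃, first mutation ν̃, cell death β̃, second mutation
μ̃): A and B are the roots of x² − (β̃+μ̃−α̃)x − α̃μ̃ and δ = ν̃/α̃.  Defaults:
A = −0.0722, B = 1.18×10⁻³, δ = 0.0952.  Onset is sampled on a yearly
reference grid (38–92) with a distinguished "never" outcome; the weight at
grid age t is the survival mass on (t−1, t], and the residual mass goes to
"never", so weights sum to one exactly regardless of grid resolution.

*Incidence-rate adjustment.* The model is calibrated to a high-incidence
reference population; the target population's age-standardized incidence is
0.48 of the reference.  We interpret this as risk attained 0.48× earlier in
age: sampling weights come from the **unscaled** survival over the grid,
and the attained onset age is 0.48 × (grid age), i.e. onset between 18.2
and 44.2 years.  The alternative reading (evaluating the survival at scaled
ages while keeping grid ages as onset ages) is available via
`OnsetModel(scale_applies_to="evaluation")`, but it implies a lifetime
onset fraction of only 2.4% and onset ages 38–92, which is incompatible
with the diagnosed counts (~20k of 175k) and diagnosis-age quartiles
(39/47/54) this model is meant to produce; the default reading reproduces
both.  This was the single most consequential open design choice.

**Tumor growth.** Tumors are spherical, onset diameter 0.5 mm
(v₀ = πd₀³/6 ≈ 0.065 mm³), growing exponentially in volume
V(z) = v₀·e^{z/r}, where r (years) is the *inverse* growth rate: doubling
time DT = r·ln 2 (365.25 days/year).  Across women, r is gamma distributed
with shape 1/φ and a log-linear mean in BMI,

    E(R) = exp(λ0 + λ1·bmi),   Var(R) = φ·E(R)² ,

defaults λ0 = −0.015, λ1 = 0.009, φ = 1.355.  With λ1 > 0, higher BMI
means a larger time constant, i.e. *slower* growth on this convention.  A
`direct_rate` convention (V = v₀·e^{z·r}, DT = ln 2/r) is provided behind a
switch because the reverse reading of r exists in parts of the literature;
all defaults use `inverse_rate`, which is what the symptomatic-detection
closed forms below assume.

**Symptomatic detection.** Symptoms arise with hazard η·V(s) proportional
to current tumor volume (η = 6.418×10⁻⁵ per mm³·year).  The cumulative
hazard from onset is η·r·(V(s) − v₀), so inverse-CDF sampling gives, for a
uniform draw u,

    V(U) = v₀ + (−ln(1−u))/(η·r),   U′ = r·ln(V(U)/v₀),   U = T + U′,

with the symptomatic diameter d(U) = (6V(U)/π)^{1/3}.  A brute-force
discrete-time simulation of the same hazard (step 10⁻³ years) is used as a
distributional oracle in the test suite (two-sample KS).

## Screening programs

Screens occur at exact ages start, start+Δ, …, ≤ end (default 30–65;
Δ ∈ {1, 2, 3} years).  Attendance is a two-group mixture fixed per woman:
80% of women attend each screen independently with probability 0.90, 20%
with probability 0.15 (population-average attendance 0.75); a `perfect`
mode attends everything.  An attended screen with an existing
pre-symptomatic tumor detects it with probability
logistic(β0 + β1·d(x)) — moderate profile (−5.04, 0.56): P = 0.5 at
9.0 mm; high profile (−4.67, 0.65) — via independent Bernoulli draws.
The BMI risk-based program applies the high profile to obese women only.

**Outcome classification.** The first positive screen before the latent
symptomatic age yields a screen detection.  A woman who reaches her
symptomatic age U ≤ 65 undetected is an *interval* cancer if she attended
at least one prior negative screen, else a symptomatic diagnosis outside
the program's reach.  Tumors neither detected nor symptomatic by the
horizon are undiagnosed.  An optional stricter interval definition requires
the negative screen to have occurred while the tumor existed.

**Analysis cohort and horizon.** The disease cohort is restricted to
tumors with onset inside the screening window [30, 65], and symptomatic
diagnoses are counted up to age 65 (the end of screening) in both arms.
Both choices were open; they were fixed because they jointly reproduce the
scale and age structure of the unscreened comparator this model is built
to match (≈21.5k diagnoses per 175k women; diagnosis-age quartiles ≈
40/45/52; symptomatic size bands ≈ 3/16/55/26% across <10/10–19/20–50/≥50
mm).  A wider horizon (e.g. 92) and the weaker exclusion rule (only
symptomatic-before-start lost to follow-up) remain configurable.

**Paired arms.** The no-screening comparator shares the screening arm's
natural histories (common random numbers), so the % change and
% overdiagnosis columns

    %change = 100·(n_scr − n_no)/n_no,   %overdiag = 100·(n_scr − n_no)/n_scr

are not inflated by Monte-Carlo noise.  Overdiagnosed cases are
screen-detected tumors that would never have surfaced by the horizon.

## Competing-risks analysis

Event records run from tumor onset: status 1 = screen-detected, 2 =
interval-detected, 0 = censored (undetected at 65; symptomatic diagnoses
outside the program leave the risk set at their diagnosis age).  The whole
analysis assumes a maximum detected tumor size of 50 mm: detected records
above it are dropped before estimation (censored records are kept).

*Cause-specific Cox models* (lifelines, Efron ties) treat competing events
as censored at their event time; BMI category enters as dummies against
the underweight reference, optionally with age at detection/censoring.
*Cumulative incidence* uses a vectorized Aalen–Johansen estimator,
CIF_k(t) = Σ_{s≤t} S(s−)·dN_k(s)/Y(s), with exact handling of the heavy
ties the yearly onset grid produces (screen-detection times are integers);
it satisfies Σ_k CIF_k + S = 1 at every event time.  *The K-sample CIF
test* is a Gray-type (ρ = 0) score test on the subdistribution hazard:
competing-event subjects remain in the risk set with inverse-probability-
of-censoring weights G(t−)/G(T_i−) from the pooled censoring Kaplan–Meier,
and the statistic uses a hypergeometric-type working variance on K−1
components.  With a single cause and no censoring it reduces exactly to
the standard log-rank test (verified against lifelines); identical groups
give a statistic of exactly zero.

## Growth-rate estimation

`GammaGrowthModel` fits (λ0, λ1, φ) by full maximum likelihood for
directly observed (bmi, r) pairs — gamma with shape 1/φ and log-link mean —
with φ estimated on the log scale (BFGS, Nelder–Mead polish).  Confidence
intervals are percentile bootstrap over case resamples (default 1000;
failures excluded and counted).  The clinical data behind the published
estimates are not deposited, so this module's correctness is established
by parameter recovery on synthetic draws (within 3 bootstrap SEs at
n = 5000) and by agreement of the mean parameters with statsmodels' Gamma
GLM as an independent oracle.  At the clinical sample size (n = 187) the
λ1 interval usually includes 0, mirroring the reported uncertainty.

## Synthetic study data

Two generators make every stage testable without a download.
`generate_clinical_fixture` emulates the undeposited 187-patient series:
truncated-normal marginals whose *truncated* moments match the published
mean/SD/range for tumor size (51.38 ± 30.35, 10–130 mm), BMI
(29.73 ± 7.46, 14.96–67.46) and age (51 ± 12, 26–85), joined by a Gaussian
copula with a small default BMI–size correlation (0.1) that is
configurable and never load-bearing in tests.  `generate_growth_observations`
draws (bmi, r) pairs from the gamma regression itself for recovery
testing.  These fixtures match marginal moments and the model's own
conditional structure only; they carry no patient-level realism (no
histology, no joint dependence beyond the copula), so passing tests
demonstrate internal consistency of the pipeline, not fidelity to the
original patients.

## Problem sizes and runtime

All headline quantities are computed at the study's full scale — 175,000
women per scenario (35 yearly cohorts × 5,000 births) — which takes about
one second per paired run; the pooled tumor-characteristic summaries use
twelve such runs (4 BMI scenarios × 3 interval strategies) and the
competing-risks analysis pools ten general-population replicates
(≈210,000 filtered event records).  Property tests use smaller populations
(500–2,000 births per cohort) where only distributional shape matters.

## Known limitations

- Single tumor per woman; no other-cause mortality, no secular BMI trends,
  no breast-density or false-positive modeling.
- The onset-grid incidence adjustment is an interpretation of an
  under-specified calibration (see above); the alternative reading is
  preserved behind a switch.
- The detection-mode shares and conditional summaries (doubling time,
  presence time) depend strongly on the interaction between per-screen
  sensitivity and sojourn time; the two interval-cancer definitions
  provided bracket the plausible conventions, and the conditional
  summaries differ materially between them.
- The Gray-type test's working-independence variance ignores the
  correlation induced by the IPCW weights; its size is exact only in the
  no-competing/no-censoring reduction, and it is otherwise used as a
  descriptive ordering statistic.
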