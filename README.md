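# bcscreen

Microsimulation of breast-cancer natural history and mammography screening
for populations with different body-mass-index (BMI) distributions.

Screening programs trade off early detection against overdiagnosis, and the
balance depends on how fast tumors grow.  If tumor growth varies with BMI,
then so do the yields of annual, biennial and triennial screening — and a
single one-size-fits-all interval may serve heavier and leaner women
differently.  `bcscreen` is for biostatisticians and screening modelers who
want a tested, reproducible pipeline for exploring that question: it
simulates each woman's tumor onset, growth and symptomatic surfacing,
overlays screening schedules with imperfect attendance and size-dependent
test sensitivity, and summarizes the outcomes descriptively and with
competing-risks survival analysis.

## Model

For each woman:

- **Onset age** T follows a two-stage clonal-expansion (MVK) survival
  function F_T(t) = [(B−A)e^{Bt}/(Be^{(B−A)t}−A)]^δ with
  (A, B, δ) = (−0.0722, 1.18×10⁻³, 0.0952), sampled on a yearly grid with a
  "never" outcome and an incidence-ratio age adjustment (×0.48).
- **Growth**: tumor volume V(z) = v₀·e^{z/r} from a 0.5 mm sphere; the
  inverse growth rate r ~ Gamma(shape 1/φ) with log-linear mean
  log E(R) = λ0 + λ1·bmi, (λ0, λ1, φ) = (−0.015, 0.009, 1.355).
  Doubling time DT = r·ln 2.
- **Symptomatic detection**: hazard η·V(s) with η = 6.418×10⁻⁵, inverted in
  closed form: V(U) = v₀ + (−ln(1−u))/(η·r), U′ = r·ln(V(U)/v₀).
- **Screening**: screens every 12/24/36 months over ages 30–65; attendance
  mixture 0.8@0.90 + 0.2@0.15 per screen; per-screen detection probability
  logistic(β0 + β1·d(x)) in tumor diameter (moderate: P = 0.5 at 9 mm;
  high profile optionally for obese women).

Outcomes per woman — screen-detected, interval (symptomatic after a
negative screen), symptomatic outside the program, or undiagnosed — feed
program comparisons (% change, % overdiagnosis, detection-mode shares),
size-band and doubling-time tables, and competing-risks analyses
(cause-specific Cox hazard ratios by BMI category, Aalen–Johansen
cumulative incidence, a Gray-type K-sample CIF test).

## Worked example

```python
from bcscreen import ScreeningSimulation, RunConfig, CohortSpec, BMI_SCENARIOS

cfg = RunConfig(cohorts=CohortSpec(1986, 2020, 5000),       # 175,000 women
                scenario=BMI_SCENARIOS["normal"])           # BMI ~ N(21.5, 0.5)
res = ScreeningSimulation(cfg).run(seed=7)                  # biennial program
print(res.summary())
```

```
scenario                  normal
no_screening               21129
screening                  22520
pct_change              6.583369
pct_overdiagnosis       6.176732
pct_screen_detected    57.704263
pct_interval           36.452043
```

Of 175,000 normal-weight women, 21,129 would surface symptomatically by age
65 without screening; the biennial program diagnoses 22,520 — a 6.6%
increase, meaning 6.2% of screening-arm diagnoses are overdiagnosed tumors
that would never have surfaced.  57.7% of diagnoses are made at a screen
and 36.5% are interval cancers.  The conditional tumor biology differs
sharply by detection mode:

```python
print(res.doubling_time[res.doubling_time.bmi_category == "normal"])
```

```
bmi_category     mode     n  mean    sd    q1  median    q3
      normal   screen 12995 308.0 247.8 124.9   245.1 427.9
      normal interval  8209 122.0 160.4  17.1    54.8 158.7
```

Screen-detected tumors double in ~245 days (median) versus ~55 days for
interval cancers — length-biased sampling: slow tumors linger in the
screen-detectable window, fast ones surface between screens.  The interval
cancers' median presence time (onset to symptoms) is 2.8 years
(`res.presence_time`).

The same objects drive the competing-risks stage:

```python
from bcscreen import encode_events, fit_cause_specific_cox, estimate_cif

events = encode_events(res.histories, res.outcomes, end_age=65,
                       max_detected_size_mm=50)
fit = fit_cause_specific_cox(events, cause="screen", adjust_for_age=True)
cif = estimate_cif(events)["normal"]
```

A command-line interface mirrors the library
(`bcscreen simulate|summarize|analyze|estimate|sweep|make-fixtures`), with
YAML configuration and a manifest that makes every run bit-reproducible.
`bcscreen sweep` reruns a scenario with the onset or sensitivity parameters
scaled by ±10% and tabulates the outcomes side by side.

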