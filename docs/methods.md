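# Methods

## Problem and pipeline

`circawarn` analyses daily home-telemonitoring data from cancer patients
on chemotherapy and builds an early-warning rule for emergency
(unplanned, mostly toxicity-related) hospitalizations.  Three parameter
groups are monitored per patient-day: self-measured morning body
weight, the 19-item MD Anderson Symptom Inventory (MDASI; 13 symptom
severity items and 6 daily-life interference items, each 0–10,
completed in the evening), and continuous wrist actigraphy (activity
counts per 1-minute epoch) summarized as the circadian dichotomy index
I<O.  The pipeline stages are:

1. **Actigraphy → I<O.**  I<O is the percentage of in-bed epochs whose
   activity counts are *strictly* below the median count of the
   out-of-bed epochs.  It is computed over 72-hour records using 3-day
   sliding windows, one value per monitored day.  Healthy adults almost
   always show I<O ≥ 98%; circadian disruption lowers it.
2. **Timeline assembly.**  Per patient-day: weight change in percent of
   a pre-treatment baseline (mean of the weights measured before the
   first chemotherapy course), the 19 MDASI items, I<O, hospitalization
   flags, and per-parameter availability flags.
3. **Compliance accounting.**  Rates of transmitted patient-days per
   parameter, for at least one parameter, and for the full set, over a
   per-protocol period (first 30 monitored days by default) with
   hospitalization days removed from the denominator; plus a rolling
   statistic (full set available at least once per trailing 3 days).
4. **Feature engineering.**  Each of the 21 daily series (19 MDASI,
   weight change, I<O) is completed by interpolation — leading/trailing
   gaps copy the nearest measured value, interior gaps are linear —
   and reduced to its short-term dynamics `d[t] = x[t] − mean(x[t−1],
   x[t−2], x[t−3])`.  The first 3 days per patient are warm-up and
   excluded from modelling, as are in-hospital days.
5. **Discriminant model.**  A two-class linear discriminant on the 21
   standardized dynamic features.  Positive class: the 3 home days
   preceding an unplanned admission.  Training uses patient-days with
   day number ≤ 30; evaluation uses either all valid days
   (`mode="whole"`) or only later days (`mode="split"`).

## The discriminant in detail

With pooled within-class covariance `S_w`, class means `μ₀, μ₁` of the
standardized features, and a relative ridge `λ` (default `10⁻⁶`), the
coefficient vector is

    w = (S_w + λ·mean(diag(S_w))·I)⁻¹ (μ₁ − μ₀)

The ridge guards near-singularity: 21 features against a handful of
pre-admission days makes `S_w` poorly conditioned.  Standardization
(sample mean/SD of the training rows) is on by default so that
coefficients are rank-comparable across items on different scales;
constant features keep scale 1.

The decision cut on the score `s = wᵀz` follows the Gaussian
equal-covariance rule: with priors `(π₀, π₁)` the threshold is

    t = (m₀ + m₁)/2 + σ²·log(π₀/π₁)/(m₁ − m₀)

where `m_k = wᵀμ_k` and `σ² = wᵀS_reg w`.  `fit_lda` defaults to equal
priors (the plain midpoint), which keeps the closed-form toy examples
transparent.  `run_experiment` defaults to *empirical* training-class
priors.  This is a deliberate design choice: pre-admission days are
rare (a few percent of patient-days), and a midpoint cut on such
imbalanced data flags an unacceptable fraction of ordinary days —
with a pure-noise discriminant direction the midpoint sits only
`√D̂²/2` score-SDs above the negative-class mean, yielding ~30–40%
false alarms.  The prior-shifted cut brings the false-alarm rate in
line with the rarity of the event, and makes the null behavior sane:
on cohorts with no planted deterioration, accuracy matches the
majority-class rate.  An explicit `threshold=` override is available
for exploring other operating points.  Score ties classify negative
(conservative for an alarm system).

The discriminant is deterministic; no randomness enters the fit.

## Synthetic cohorts

No raw patient data accompany the analysis, so a generator produces
cohorts with the structure the pipeline assumes.  Defaults describe the
study-like condition: 31 patients, 60 monitored days each, 1-minute
epochs, bed window 23:00–07:00, ~3 chemotherapy courses per patient
(4 days long, 14 days apart, first course on day 5, ~35% given in
hospital as planned admissions), and a 10% probability that a course is
followed by an emergency admission 3–10 days after it ends (stay 2–9
days).  Hospital days carry no home data.

*Activity counts* are negative binomial — the standard over-dispersed
model for accelerometer counts — with mean 150 counts/min out of bed
(k = 3), modulated sinusoidally ±30% with an afternoon peak, and mean
10 counts/min in bed (k = 0.4, heavy-tailed to produce occasional
restless minutes).  Under these defaults the 3-day I<O is ≥ 98 for
virtually every healthy window, matching the healthy-control range of
the index.

*Weight* starts at a patient-level baseline (N(70, 10) kg, clipped to
45–110) and follows a small random walk (SD 0.1 kg/day).  *MDASI
items* fluctuate (SD ≈ 1 point, rounded and clipped to 0–10) around
item-typical levels plus a patient offset.

*Pre-admission deterioration.*  Over the `onset_lag_days` (default 14)
before an emergency admission, a quadratic ramp `f = (t/lag)²` scales:
the in-bed activity mean by `1 + 8f` (driving I<O down to roughly 80%
at admission), the daytime mean by `1 − 0.3f`, body weight down by
`3f` percent, and five circadian-disruption-linked items (fatigue,
lack of appetite, general activity, work, relations with others) up by
`3f` points.  The quadratic shape makes the decline slow early and
steepest in the final days, concentrating the dynamic signal in the
3-day warning window.  These effect sizes are free parameters of the
generator: the source analysis reports the pre-event decline only
graphically, so the defaults are this package's own choice of a
plausible magnitude, not estimates.

*Missingness* is missing-completely-at-random per parameter per day
(weight 18%, MDASI 22%, actigraphy 25% — chosen to match per-parameter
compliance in the high-70s/low-80s).  MDASI missingness is
questionnaire-level: a submitted questionnaire has all items.

Each patient's random stream derives from `(seed, patient_index)`, so a
given patient's data are reproducible regardless of cohort size.

What the generator does **not** emulate: informative missingness
(sicker patients skipping measurements), weekly/weekend rhythms,
device artefacts, napping or irregular bed times, inter-item MDASI
correlation beyond the shared deterioration ramp, and
chemotherapy-cycle-locked symptom oscillation.  Passing tests
therefore demonstrate the correctness of the pipeline's computations
and its ability to recover a planted signal of realistic shape — not
clinical validity on real cohorts.

### Benchmark scenarios

`strong_signal_config()` is a compact recovery benchmark: 10 patients,
40 days, courses every 10 days with a 60% per-course event
probability, and a short steep ramp (lag 5 days, in-bed mean ×13 at
peak, 5% weight loss, +5 MDASI points).  The early-warning model
should — and does — recover this signal (median sensitivity ~80%,
specificity ~99% over 50 cohorts).  Zeroing the effect sizes gives the
matched null scenario, on which accuracy should track the
majority-class rate.  Cohort sizes here are scaled for quick, repeated
simulation while keeping ≥ 200 patient-days per cohort.

## Numerical and convention choices

- **Median** of an even number of out-of-bed counts: mean of the two
  central order statistics (numpy convention).
- **Strict inequality** in I<O: epochs equal to the median do not
  count as rest.
- **Trailing windows** for both I<O and the rolling compliance
  statistic: a day's value never uses future data, as required for
  prospective warning.
- **Window coverage**: an I<O value is emitted only when ≥ 50% (by
  default) of both the in-bed and the out-of-bed epochs of the 72-h
  window are observed; otherwise the day is missing and later
  interpolated.
- **Quartiles** in descriptive tables: linear interpolation between
  order statistics (numpy/pandas default, "type 7").
- **Warm-up**: the dynamics transform is undefined for the first 3
  days; those rows are flagged invalid rather than imputed.
- **Labels**: day `d` is positive iff an unplanned admission occurs at
  `a` with `1 ≤ a − d ≤ 3`; in-hospital days are never positive and
  never enter the evaluation set.
- **Baseline weight** uses all weights observed before the first
  course (flagged when fewer than 3); if none exists the first
  observed weight is used and flagged, so a sparse patient does not
  abort a cohort run.
- **Degenerate windows** (no in-bed or no out-of-bed epochs) raise
  distinct error codes at the primitive level and become missing
  values at the series level.
- **SEM** in pre-event summaries uses the sample SD over events
  (ddof = 1); with one contributing event it is undefined and reported
  missing, never zero.

## Known limitations

- The compliance "rolling 3-day" statistic is defined per patient-day;
  a per-patient definition would give different numbers and the choice
  is a convention, not a derivation.
- The in-bed annotation must be supplied per epoch; the clock-window
  fallback (`bed_window_mask`) is a labelled heuristic, not a sleep
  scorer.
- The discriminant's absolute coefficient values depend on the
  standardization and class-coding conventions; only their relative
  magnitudes are meaningful, and no clinical validity is claimed.
- Patient-day splitting (not patient-level cross-validation) is the
  default evaluation, mirroring the learning/validation design it
  reimplements; `mode="split"` gives the out-of-sample view but is
  still within-patient.
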