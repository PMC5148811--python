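# circawarn

Circadian telemonitoring analytics and 3-day early warning for
home-chemotherapy cohorts.

Cancer patients receiving chemotherapy at home can transmit three kinds
of data daily: self-measured body weight, the 19-item MD Anderson
Symptom Inventory (MDASI), and wrist actigraphy (activity counts per
1-minute epoch).  `circawarn` implements the full analysis of such a
telemonitoring stream for biostatisticians and digital-health
researchers:

- the **circadian dichotomy index I<O** — the percentage of in-bed
  epochs with activity strictly below the median out-of-bed activity —
  computed over 72-h records with 3-day sliding windows (healthy
  values rarely fall below 98%);
- **daily timelines** of body-weight change vs. a pre-treatment
  baseline and the 19 MDASI items, with hospitalization accounting;
- **platform-use compliance** rates (per parameter, at-least-one,
  full-set, and rolling 3-day full-set) over per-protocol and
  extension periods;
- **feature engineering** for prediction: edge/linear interpolation of
  each of the 21 daily series, then the dynamic change
  `d[t] = x[t] − mean(x[t−1..t−3])`;
- a **linear discriminant early-warning model** (ridge-stabilized
  pooled-covariance LDA, `w = (S_w + λI·mean diag)⁻¹(μ₁ − μ₀)`) that
  flags the 3 home days preceding an unplanned hospitalization, with
  sensitivity/specificity/PPV/NPV/accuracy reporting;
- a **synthetic-cohort generator** (negative-binomial activity counts
  with circadian modulation, MCAR missingness, chemotherapy courses,
  planted pre-admission deterioration) so every stage is testable
  without patient data.

See `docs/methods.md` for the model details and conventions.

## Worked example

Simulate a small cohort with frequent toxicity events, build features,
fit and evaluate the early-warning model, and account for compliance:

```sh
cat > sim.yaml <<EOF
n_patients: 8
n_days: 40
courses_per_patient: 3
course_spacing_days: 10
first_course_day: 5
event_probability_per_course: 0.5
event_delay_range: [3, 8]
deterioration.onset_lag_days: 6
deterioration.night_activity_effect: 10.0
deterioration.weight_loss_pct: 4.0
deterioration.mdasi_drift: 4.0
EOF
circawarn simulate --config sim.yaml --seed 7 --out data
circawarn features --data-dir data --out features.csv
circawarn train --features features.csv --out-dir model
circawarn compliance --data-dir data --period 1:30 --out compliance.csv
```

which prints:

```
INFO circawarn: feature matrix: 320 rows (212 valid, 36 positive)
sensitivity=97.2%  specificity=97.2%  ppv=87.5%  npv=99.4%  accuracy=97.2%
theoretical=180  full=48.9%  at_least_one=100.0%  weight=82.8%  mdasi=82.8%  actigraphy=75.0%  rolling3_full=80.0%
```

Reading this: of 320 patient-days, 212 are usable for modelling (the
rest are warm-up or in-hospital days) and 36 fall in the 3-day window
before an unplanned admission.  Fitted on the first 30 days and
evaluated on the whole span, the discriminant catches 97% of
pre-admission days while flagging 2.8% of ordinary days — a strong
planted signal is easy; real data are not this clean.  The compliance
line says that of 180 theoretical patient-days (monitored days minus
hospital stays) in the per-protocol period, 48.9% had all three
parameter groups and 100% had at least one.

The fitted model is plain JSON (`model/model.json`); ranked
coefficients are available via `circawarn report` or:

```python
from circawarn.lda import LDAModel, rank_coefficients
print(rank_coefficients(LDAModel.from_json("model/model.json")).head())
```

```
        parameter  coefficient
    weight_change    -3.372645
               io    -1.432713
numbness_tingling    -0.912633
         vomiting     0.522570
          fatigue     0.474847
```

Negative weight-change and I<O dynamics (falling weight, falling
dichotomy index) dominate this fit, as planted.

The same stages are available as library calls
(`circawarn.simulate_cohort`, `assemble_timeline`, `assemble_features`,
`run_experiment`, ...), which is the more convenient interface for
scripted studies.

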