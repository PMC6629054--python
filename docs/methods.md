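# Methods

This note documents the models, the synthetic-data generator, and the
numerical and design choices behind `akipredict`, in enough detail to judge
what a passing test suite does and does not demonstrate.

## AKI labeling

AKI is defined from inpatient serum creatinine alone.  The two KDIGO
creatinine criteria are evaluated at every measurement time `t` that has at
least one strictly earlier measurement:

* **absolute**: `Cr(t) − min Cr over [t−48h, t) ≥ 0.3 mg/dL`;
* **relative**: `Cr(t) ≥ 1.5 × min Cr over [t−168h, t)` (the *rolling
  baseline*, the lowest value over the preceding 7 days).

Both windows are half-open and exclude the current measurement.  Including
the current value would let the relative criterion compare a measurement to
itself whenever it is the running minimum; exclusion also matches the plain
reading of "preceding".  Consequences worth knowing:

* No onset can ever occur at a patient's first measurement (no comparator),
  so AKI requires at least two measured creatinine values by construction.
* When the baseline window is empty the baseline is *undefined* (NaN), never
  zero.
* Only the first event per admission is detected; everything at or after
  onset is censored downstream.

**Staging** uses the guideline thresholds — stage 2 at ≥ 2.0× baseline,
stage 3 at ≥ 3.0× baseline or an absolute value ≥ 4.0 mg/dL — evaluated at
the onset measurement, boundaries inclusive at their lower edge.  Staging by
dialysis initiation is out of scope here because renal replacement therapy is
treated as a prediction outcome, not a stage input.  **Sustained AKI**
requires the onset measurement *and* the next measurement to each satisfy a
criterion against their own windows; an onset at the last measurement of an
admission is never sustained.

All mg/dL comparisons carry a 1e-9 tolerance so that float representation
cannot flip a decision at exactly 0.3 or exactly 1.5×.  Simultaneous
duplicate timestamps collapse to their maximum value (deterministic, and
conservative toward detection).  The detector is verified exactly — onset
time, criterion, stage, sustained flag — against an independent O(n²)
all-pairs implementation on 10,000 fuzzed series.

## Cohort rules

A hospitalization is included iff the discharge time is present, at least
two inpatient creatinine values exist, no ESKD code is flagged, and the
admission creatinine is < 4.0 mg/dL.  "Admission creatinine" is the
chronologically first inpatient value — the only definition computable from
the data as described.  ESKD arrives as a boolean column: ICD code lists are
institution-specific and belong in upstream ETL, not in the analysis rule.
Attrition is attributed sequentially (first rule wins), as in a cohort flow
diagram.

## Observation matrix

One row per distinct event timestamp (laboratory measurement or exposure
onset).  Time-varying covariates are carried forward until remeasured; rows
before the first creatinine measurement carry a missing creatinine state.
Exposures (medications and procedures) are absorbing within the admission:
once exposed, always exposed.  Three creatinine features are derived per row:

* `last_creatinine` — latest value at or before the row time;
* `baseline_creatinine` — the 7-day rolling baseline (strictly before the
  row time; missing until a second-in-window value exists);
* `delta_creatinine_48h` — `last_creatinine` minus the 48-hour window
  minimum, defined as 0 when the window holds no prior value.  This mirrors
  the absolute KDIGO criterion's reference value.

Labels use a half-open lookahead `(t, t+24h]`: a row exactly at onset is
censored (the onset measurement already shows the rise and would leak), a
row exactly 24 h before the event is positive.  The same machinery labels
sustained AKI, renal replacement therapy, and death; admission-level
("any during stay") variants are emitted alongside for summary tables.

Missingness is never imputed.  Each covariate class drops rows missing any
covariate it requires (complete case); demographics are complete by
construction and drop nothing.

The covariate registry holds 35 covariates in five classes — 9 demographics
(age, sex, race, surgical admission, CHF, hypertension, diabetes, liver
disease, Elixhauser score), 10 laboratory values (bicarbonate, BUN,
chloride, baseline and last creatinine, hemoglobin, potassium, sodium, WBC,
platelets), 9 medications, 6 procedures, and the 48-hour creatinine delta.
The laboratory *model* includes the delta (it is a laboratory-derived
quantity); the delta is additionally modeled alone because of its strong
marginal performance.

## Risk models and inference

Each covariate-class model is a plain logistic regression on the row-level
24-hour label — the discrete-time hazard formulation, in which every row
contributes one Bernoulli term.  Fitting is IRLS with step-halving (the
log-likelihood is non-decreasing across accepted iterations), convergence at
relative log-likelihood change < 1e-8, and a cap of 100 iterations.  There
is no regularization: complete separation is reported as an error naming the
diverging covariate (|log-odds| > 30 is the divergence bound), and a
rank-deficient design is an error listing the collinear columns.  Continuous
covariates enter untransformed.

Within-patient rows are dependent, so the covariance is the cluster-robust
sandwich with patients as clusters: per-row scores `x_i (y_i − p_i)` are
summed within patient before the outer product.  A small-sample factor
G/(G−1) is applied by default (statsmodels additionally applies
(n−1)/(n−k); the two agree within 1% on realistic sizes, and the in-house
estimator reduces exactly to HC0 with one row per cluster and the factor
off).  Covariate importance is ranked by |Wald z|, ties broken
alphabetically for determinism.  Models are refit per outcome rather than
re-scored, and every fit serializes to JSON; the linear predictor also
exports as a closed-form text equation that round-trips to 1e-9.

At desk-scale cohorts (thousands of patients rather than hundreds of
thousands), rare binary covariates with zero events can show quasi-separated
coefficients with inflated |z|; the pipeline driver records genuinely
unfittable or unevaluable (class, outcome) cells — e.g. renal replacement
therapy with a handful of positive rows — and continues, rather than
aborting the run.  The underlying fit and evaluation APIs still raise.

## Evaluation

AUC is the midrank Mann–Whitney statistic (ties half); the ROC staircase is
built over all unique score thresholds, and its trapezoidal area equals the
midrank AUC by construction.  Confidence intervals are a percentile
bootstrap over *patients* (B = 2,000 by default; pipeline runs use smaller B
for speed), with single-class resamples redrawn and counted.  The cluster
bootstrap was chosen because it is assumption-light; in the
independent-single-row limit it reproduces DeLong-style analytic widths
within 20%, and duplicating every patient's rows leaves it unchanged where a
row bootstrap would spuriously shrink by √2 — both properties are asserted
in the test suite.  Operating points pick the threshold whose achieved
sensitivity (or specificity) is closest to the target from the feasible
side, ties toward higher specificity, and the PPV of a cut-point is
`sens·prev / (sens·prev + (1−spec)(1−prev))`.

## Synthetic EHR generator

The generator defines the study conditions for all simulation-based tests.
Defaults, chosen once to resemble a general US inpatient population:

| quantity | default | rationale |
|---|---|---|
| length of stay | 24 h + Exp(96 h) | median ~3–4 days, heavy right tail |
| lab panels | 1 admission panel + Poisson(2/day) | daily-to-twice-daily draws |
| baseline creatinine | lognormal(log 0.9, 0.25) | median 0.9 mg/dL |
| generative hazard tick | 6 h | coarse enough for speed; several ticks per 24 h window |
| hazard (per tick) | logit p = −4.4 + 0.015·age + 0.03·BUN − 0.08·bicarbonate + 0.6·CHF + 0.7·ICU + 0.45·diuretic | ~15–18% patient-level incidence at the reference hospital |
| hospitals | H1/H2/H3, weights .54/.26/.20, intercept shifts 0/−0.15/−0.6 | per-hospital incidence heterogeneity |
| post-onset creatinine | +0.8 mg/dL per 24 h for 72 h, then plateau | lets both KDIGO criteria trigger |
| non-creatinine labs | patient-level mean + within-patient noise | carry-forward has something to carry |
| exposures | absorbing, onset uniform in stay, typical inpatient prevalences | matches carry-forward semantics |
| deliberate exclusions | 2% missing discharge, 2% ESKD, 1% admission Cr ≥ 4, 2% sparse labs | the cohort filter has work to do |
| RRT | 5% of AKI, 6–48 h after onset | short lag keeps 24 h-lookahead labels attainable under post-onset censoring |
| death | 2% baseline, +5% with AKI, in the last 30% of the stay | plausible inpatient mortality |

The ground truth returned with each cohort contains the true onset times,
the generative coefficients, and the full person-period frame (true
covariate state, per-tick probability, event indicator), so parameter
recovery is a direct logistic fit on that frame: over 200 replicates of
5,000-patient single-hospital cohorts, each coefficient's 95% cluster-robust
Wald interval covers its generative value ≥ 92% of the time.

What the generator does **not** emulate: measurement-driven (informative)
sampling, vitals waveforms, drug dose/duration, inter-hospital transfer,
outpatient baselines, or any claim of reproducing a specific hospital
system's demographics.  Post-onset creatinine always rises for 72 h, so
nearly every detected event is sustained — real cohorts show far more
transient AKI.  Detection sensitivity for generated onsets is ~60–70% at the
default sampling rate (a 0.3 mg/dL rise takes ~9 h to accrue, and late
onsets may have no subsequent draw), which is the realistic behavior of
creatinine-based surveillance, not a defect of the detector — the detector
itself is oracle-exact.  Passing simulation tests therefore demonstrate
correctness of the machinery under a known hazard, not clinical performance
on real data.

## Problem sizes

Simulation-based tests and the acceptance script use cohorts of 150–5,000
patients and bootstrap sizes of 100–2,000, sizes at which every documented
property is stable across seeds while the whole suite runs in minutes on one
CPU.  The headline AUCs of a real deployment (computed on millions of rows)
are out of reach of any desk-scale simulation and are not claimed.

## Known limitations

* The rolling baseline uses inpatient values only; patients presenting with
  community-acquired AKI and no recent creatinine are missed by design.
* Whether a real deployment's staging should use onset-time or peak-vs-
  baseline values is site policy; this package stages at onset and exposes
  the per-admission maximum stage only through the event table.
* The bootstrap CI method is one defensible choice among several
  (cluster-jackknife, DeLong with cluster correction); cross-method numeric
  agreement beyond the independent-rows limit is not claimed.
* No calibration analysis (Brier score, calibration slope) — discrimination
  only.
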