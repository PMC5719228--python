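# Methods

`icuward` implements a complete, testable pipeline for predicting unplanned
transfers from a pediatric inpatient floor to the ICU from EHR event
streams: a synthetic data generator with known ground truth, heuristic
case/control cohort construction, time-windowed feature extraction,
regularized classifiers trained on the penalized likelihood, and a
prediction-horizon evaluation harness. This note records the model, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Problem and cohort definitions

The unit of analysis is the ICU *transfer*, not the patient. Candidate
cases are floor→ICU adjacencies in admission–discharge–transfer (ADT)
data; transfers originating in the ED, OR, PACU, or ICU are excluded, as
are transfers into the NICU. Because no EHR field marks a transfer as
"unplanned", a candidate becomes a case when at least one of five
heuristic urgency criteria fires in a closed window around the transfer
(default [−2 h, +12 h]):

1. initiation of CPAP/BiPAP or invasive ventilation,
2. vasopressor administration,
3. an NS/LR fluid bolus at or above a volume threshold (default 20 mL/kg),
4. an emergent procedure / resuscitation event,
5. an ICU-only medication on the medication administration record.

The criteria are configuration (attribute lists, windows, thresholds in
`cohort.DEFAULT_CRITERIA`), because their institutional definitions are not
portable; the engine that evaluates them is what the package tests. Cases
with positive-pressure ventilation, vasopressors, fluid resuscitation, or
emergent procedures inside [−2 h, +12 h] are additionally flagged as
critical deterioration events (CDE), a subset of cases by construction.

Controls are encounters never in an ICU with ≥24 h of floor time, sampled
so that per-stratum (age bin × diagnosis group) counts are proportional to
the case distribution at roughly 1:5 cases:controls. Empty strata fall
back to the nearest age bin, then to the whole pool (logged). All records
(cases and controls) need ≥8 h of floor time; both boundaries are
inclusive, and floor hours sum across floor segments before the event.
Age bins are {<1, 1–4, 5–11, 12–17, ≥18 y}; diagnosis groups are opaque
strings.

## Feature extraction

A prediction point is `event_time − horizon`, where the event is the ICU
transfer (cases) or floor departure (controls). Lookback windows are 24 h
for vitals and 72 h for labs, acuity scores, and nursing assessments, with
a nested 6 h sub-window for acuity recency features. Windows are open at
both ends, `(t_pred − w, t_pred)`: only events strictly *before* the
prediction time are visible. This is the package's hard leakage guarantee
— perturbing anything at or after the prediction time cannot change a
feature vector — at the cost of excluding an observation charted at the
exact prediction instant (a measure-zero event in practice).

Operators per element type (names are human-readable feature strings):

* **Vitals** — least-squares slope in units/hour, |slope|, sign
  indicators, the C1–C4 binned category of the MAX/MIN/AVERAGE/NEWEST/
  OLDEST value, and a normalized category histogram (sums to 1 whenever
  any measurement exists). The average is binned after averaging. Types
  with <2 points emit no slope; with 0 points, nothing.
* **Labs** — Low/Normal/High category of each value; the (2nd-newest,
  newest) category pair; change/no-change; indicator bins for the
  newest/oldest and newest/2nd-newest value ratios at >{1.25, 1.5, 2.0,
  3.0} and <{0.8, 0.67, 0.5, 0.33} (omitted when the reference is 0); a
  presence indicator; the last category.
* **Acuity scores** — indicators "=0" and ">k" for k ∈ 0..9 on the
  MIN/MAX/NEWEST score; full-window and last-6 h slopes with magnitudes;
  overlapping count indicators for the number of measurements in the last
  6 h at >{0, 1, 2, 4, 6, 10}.
* **Nursing assessments** — a 0/1 indicator per attribute–value pair seen
  in the window (presence, not multiplicity) plus a NEWEST pair indicator
  per attribute.

There is no imputation: missing elements contribute no features. Scalar
features enter the vector as reals, categorical ones as 0/1 indicators.
Ties in "newest"/"2nd newest" are broken by stable (timestamp, input
order) order. Slopes are invariant to the time origin.

The C1–C4 vitals boundaries (age-stratified, with a `descending` flag for
vitals where low values are dangerous, e.g. SpO2) and lab normal ranges
ship as an editable YAML table (`data/default_binning.yaml`); they are
configuration, and correctness is tested on the operators, not the table.

The feature vocabulary (name → column) is fit on training instances only
and frozen; unseen names at evaluation time are dropped. Instances
round-trip through SVMlight files with a TSV vocabulary.

## Classifiers

The model is p(y=1|x) = logistic(H_n(…H_1(x))) with rectified-linear
layers H_i(z) = max(0, W_i z + b_i); an empty layer list is logistic
regression (the same code path, verified bit-for-bit). Training maximizes

L(D, W) = Σ_i log p(y_i|x_i) − a1‖W‖₁ − a2‖W‖₂²

over all layer weights by minibatch SGD. Choices where the formulation was
open:

* ‖W‖₂ is read as the *squared* L2 norm (standard elastic net); the code
  documents this and it is trivially switchable.
* Biases are unpenalized (standard practice; preserves calibration).
* The L1 term uses a proximal soft-threshold step rather than a raw
  subgradient, so weights reach exact zeros (implicit feature selection).
* The penalty is an absolute term on the summed likelihood, distributed as
  penalty/n per instance-step in SGD; with the weak defaults (a1=0.001,
  a2=0.01) and cohort-scale n the per-step threshold is small, so heavy
  sparsification appears only at larger a1 (monotone shrinkage in a1 is a
  tested property).
* SGD schedule: learning rate 0.5 with 0.95 per-epoch step decay,
  minibatch 32, 30 epochs — tunables exposed in `ModelHyperparams`, with
  the per-epoch penalized likelihood logged so the upward trend can be
  monitored.
* Dropout (for MLPs) elides hidden units during training with inverted
  scaling; prediction is a plain forward pass. Default MLP settings of
  interest: three hidden layers of 60/40/40 units with 50% dropout and
  a1=0.0003.
* Hidden layers initialize He-normal; output layers at zero. Training is
  deterministic under a fixed seed.

Hyperparameters can be selected by stratified 5-fold cross-validation on
mean fold auROC, with ties broken toward stronger regularization (larger
a1, then a2) and automatic re-folding if a fold loses a class.

Gradient correctness is checked against central differences at 1e-5 (away
from zero for the L1 subgradient), and elastic-net sign recovery of 10
planted informative weights among 500 features at n=5000 is an acceptance
property.

## Evaluation

* **auROC** is the Mann–Whitney statistic (ties count ½), computed from
  midranks and tested against exhaustive pair counting.
* **DeLong** structural components give the auROC standard error, 95% CIs
  (truncated to [0,1]; zero-variance inputs collapse to the point estimate
  with a warning), and a *paired* test for two models scored on the same
  instances. The SE is validated against a 10,000-replicate bootstrap.
* **Operating point**: the threshold is the largest cutoff whose
  sensitivity reaches 80%, chosen on the evaluation scores (a post-hoc
  operating point); specificity is reported there.
* **PPV** at prevalence p is sens·p / (sens·p + (1−spec)(1−p)), reported
  at p = 1.3%, the floor-wide prevalence the published operating points
  assume. The three published (sens, spec, PPV) triples that are
  internally consistent with this closed form are reproduced to two
  decimals on the percent scale.

Experiments: single-type, additive (vitals → +labs → +acuity →
+assessments), and ablation (all−X) feature sets at a fixed horizon;
per-horizon train-and-evaluate sweeps; and the cross-horizon grid scoring
every trained model at every horizon. The cohort splits temporally
(default earliest 75% trains), mirroring a train-on-earlier-years /
test-on-final-year design. Everything is deterministic under one pipeline
seed. Plots are not produced; results are returned as DataFrames that
write to CSV.

## Synthetic data: what it emulates and what it does not

The generator produces multi-unit encounters (optional ED prefix, floor
stay, ICU stay for cases), irregular vitals (per-type renewal process with
exponential gaps, mean 2 h), sparse labs (4/day across 8 analytes),
integer acuity scores (a PEWS-like 0–9 total and a 1–5 acuity level,
6/day), categorical nursing assessments from a fixed attribute–value
catalog (8/day across 6 attributes), and intervention events near the
transfer. 10% of observations are dropped at random (interventions are
exempt, so case status is not eroded); 90% of cases receive at least one
criterion-satisfying intervention, the rest emulate planned transfers.

The deterioration signal is a latent severity ramp: zero until 8 h before
transfer, rising linearly to an `effect_size` of 2.0 standard deviations
at the transfer. Vitals drift toward their abnormal direction, acuity
scores rise, assessment values shift toward abnormal vocabulary entries;
controls carry no signal, and cases and controls share the same
floor-duration law so time-on-floor itself is uninformative (this makes
the effect_size=0 null clean: a trained model then scores at chance,
verified against a label-permutation band).

These conditions were chosen once as a plausible pediatric-floor regime —
charting roughly every 2 h, daily-to-every-shift labs and scores, a
deterioration window of hours, and overt (≈2 SD) physiology at the moment
of transfer. With an 8 h onset, discrimination is high at 1–2 h horizons,
fades through 4–6 h, and sits at chance beyond 8 h; the cross-horizon
grid's diagonal dominates its off-diagonal. Those *patterns* are what the
synthetic experiments certify. What passing tests do **not** show: real
EHR performance. Real deterioration is heterogeneous in onset and shape,
charting frequency is itself informative (here it is not, by
construction), vocabularies are messier, and the published real-data auROC
values are not reproducible from synthetic data — the package makes no
claim to them.

Problem sizes used by the shipped experiments (chosen to exercise the
statistics at desk scale): the horizon-structure check uses ≥300 cases and
≥1500 controls with the full 16×16 grid; the acceptance script uses 240
cases / 1200 controls, an 11-horizon sweep, and a 4×4 grid.

## Numerical conventions and degenerate inputs

Closed criteria/CDE windows on both ends; inclusive 8 h and 24 h
floor-time boundaries; feature windows open on both ends (see above);
slopes undefined (omitted) when all timestamps coincide; lab ratios
omitted on zero references; records whose horizon exceeds their floor time
are dropped and logged; empty score groups and single-class training sets
raise; probabilities are produced by `expit`/`log_expit`, so likelihoods
are finite for finite inputs.

## Known limitations

* The five criteria and binning tables are plausible defaults, not
  institutional truth; conclusions about their clinical validity cannot
  come from this package.
* The generator's independence assumptions (age/diagnosis independent of
  deterioration risk, homogeneous sampling) make matching easy; real
  confounding is harder.
* Assessment indicators encode presence only; multiplicity is a noted
  sensitivity axis.
* PPV is an analytic translation of (sens, spec) to a fixed prevalence,
  not an empirical count on a prevalence-realistic stream.
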