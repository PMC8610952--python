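# Methods

This note records the models, conventions and design choices behind
`akiwatch`, in the order data flows through the pipeline.

## Hour grid and units

All series live on a 0-based hourly grid: hour *h* covers `[h, h+1)` since
admission, and a stay of length L hours has `ceil(L)` bins.  Urine flow is
expressed in ml/kg/h after dividing hourly volume by ideal body weight
(Devine: 50 kg for men, 45.5 kg for women, plus 2.3 kg per inch over
60 in; 2.54 cm/in exactly).  Heights under 60 in return the base weight —
Devine is undefined there, and a decreasing extrapolation would inflate
the normalized flow.  Creatinine is mg/dl.

## Preprocessing and imputation

Nurses chart urine as cumulative volumes at irregular intervals.  Each
charted volume is spread uniformly over the unrecorded interval it closes
and accumulated into the hour bins it overlaps, prorating partial bins by
overlap fraction (sub-hour behaviour is a package convention; the
redistribution rule itself only fixes whole-hour gaps).  This conserves
total volume to floating-point accuracy — a property the test suite
checks at 1e-9 relative tolerance over randomized charting patterns.
Hours covered by a multi-hour interval are flagged imputed.  Creatinine
values are dragged forward to the next draw; hours before the first draw
are back-filled from it and flagged.

Data-quality exclusions: stays shorter than 24 h, baseline sCr below
0.5 mg/dl, community-acquired AKI, dialysis, any unrecorded UO interval
longer than 9 h, any sCr gap longer than 4 days, and centers with fewer
than 50 admissions in the input cohort.  The gap limits are strict
("more than 9 h"/"more than 4 days"): a gap of exactly 9 h is filled, not
excluded.  Long gaps are still redistributed before flagging, so volume
accounting stays consistent; exclusion, not silent truncation, is the
consequence.  Community-acquired AKI is operationalized as a detected
episode whose onset falls within the first 12 h of the stay (configurable
horizon): such events predate any possible 12-h-lookback prediction, so
they are prevalence, not prediction targets.  Dialysis is a pass-through
metadata flag; no treatment records are parsed.  Baseline creatinine is
the patient's lowest ICU value across all their stays (the source data
carry no pre-admission baseline).

## AKIN stage-2/3 labeling

Oliguria windows are maximal runs of hours strictly below threshold
(0.5 or 0.3 ml/kg/h; anuria means at or below numerical zero, 1e-9), kept
when strictly longer than the required duration — "> 12 h" needs 13 full
oliguric hours.  The stage-2 creatinine band is 200–300% of baseline
inclusive at both ends (a tie at exactly 300% is stage 2; the stage-3
ratio clause is strictly above 300%).  The stage-3 absolute clause
requires sCr ≥ 4.0 mg/dl with a rise ≥ 0.5 mg/dl over a rolling 48-h
window (the AKIN convention for "acute").

The two clauses must hold together.  The guidelines do not define the
coupling precisely, so the package accepts the creatinine clause anywhere
inside the oliguria window or within 24 h after its completion
(configurable) — wide enough to tolerate lab-draw latency, narrow enough
that unrelated events do not couple.  Onset is the first hour at which
both the completed urine-duration clause and the creatinine clause hold;
when stages 2 and 3 are both satisfied at the same hour, stage 3 wins.
Among multiple candidate windows the earliest onset wins.

Case series are truncated at onset − 6 h so every prediction carries at
least a 6-h lead; with the 12-h feature lookback this makes hour 19 the
earliest usable onset, and earlier-onset cases are dropped with a logged
count.  Control series are used whole, admission to discharge or death.

## Synthetic cohort

The generator emulates what the analysis needs from real critical-care
data, with every parameter overridable:

* **Charting**: record gaps are geometric (p = 0.55, mean ≈ 1.8 h)
  truncated at 8 h so default cohorts survive the 9-h exclusion; the
  truncation point is configurable upward to exercise exclusions.  Lab
  draws every ~12 h with ±30% jitter.  Records are cumulative volumes at
  integer hours; charting boundaries are forced at episode edges (nurse
  charting tightens when a patient deteriorates), which keeps injected
  onsets crisp under gappy charting.
* **Controls**: per-patient baseline flow is lognormal (median
  1.1 ml/kg/h, σ = 0.35) with multiplicative lognormal hourly noise
  (σ = 0.25 by default), giving a right-skewed minimum-diuresis
  distribution; 35% of controls get a transient oliguric dip
  (0.35–0.48 ml/kg/h for 2–6 h) — below the oliguria threshold but far
  too short to qualify, so the labeler is genuinely exercised.  Control
  creatinine is flat up to ±3% noise and can never reach 200% of its own
  minimum, so no control can ever satisfy the joint criteria — the
  zero-false-episode property is structural.
* **Cases** (~3% of patients, Bernoulli): a globally depressed baseline
  flow (0.55–0.95 ml/kg/h) with 1–3 pre-onset dips (0.32–0.48 ml/kg/h,
  4–10 h) — severe-AKI stays show low diuresis throughout, and this
  prodrome is what makes prediction 12 h ahead possible at all — followed
  by the qualifying run placed so its duration clause completes exactly
  at the requested onset (≥ 26 h into the stay).  Stage 2: 13+ h at
  0.30–0.45 ml/kg/h with creatinine ramping to 2.2–2.8× baseline.
  Stage 3: either > 24 h below 0.3 or > 12 h of anuria; the creatinine
  *jumps* from below 200% to above 300% between consecutive lab draws, so
  the forward-filled hourly series never visits the stage-2 band and the
  labeler cannot report an earlier stage-2 onset during the longer
  stage-3 run.  Half the anuric stage-3 cases exercise the absolute
  ≥ 4.0 mg/dl clause instead (high baseline, ratio kept inside 200–300%);
  this variant is only paired with anuria, whose urine clause completes
  at the same hour as stage 2's, so the tie resolves to stage 3.
  Dips stay above 0.3 ml/kg/h and below 11 h, and inter-dip flow sits
  above 0.5, so no urine clause can complete before the injected run at
  noise-free settings — the basis of the exact label-recovery test
  (100% stage agreement, onset within ±1 h, on 500 noise-free cases).
* Heights 150–195 cm, ~63% male; admission dates arbitrary.

What the generator does **not** emulate: fluid therapy and diuretics
(which decouple UO from renal function), sepsis/vasopressor physiology,
creatinine dilution, inter-center case mix, or the marginal distributions
of any real cohort.  Passing benchmarks on this cohort shows the
machinery is correct and that a constructed oliguric signal is found; it
says nothing about discrimination on real ICU data, where the reported
AUCs of this kind of model are substantially lower than the near-ceiling
values seen here.

## Models

**Multi-feature logistic.**  Features f_w, w ∈ [2, 12]: the minimum over
all length-w windows (within hours [0, t)) of the mean flow; prediction
hours start at t = 12.  Candidate rows are every eligible hour (cases:
every hour of the truncated series); one row per patient is then sampled
uniformly so the fit sees independent patients.  The fit is plain MLE
(scikit-learn, C = ∞); an L2 switch exists for separable toy data.  The
feature table uses a running-minimum fast path that is tested equal to
direct per-hour recomputation.

**Single-feature rule.**  Alarm iff f_w < θ_w, strictly.  The published
θ_w table (0.251 … 0.487 ml/kg/h for w = 2 … 12, with w = 7 at 0.372 the
best-performing) ships as fixed constants; on synthetic cohorts these
thresholds sit below most of the constructed signal, so the fixed rule
runs at low sensitivity/high specificity there — its continuous AUC (via
−f_w as score) is the fairer summary and is what the benchmark compares
against.

**Convolutional risk score.**  Input: the last 12 hourly flows.  Two
stacked blocks; each runs parallel same-padded 1-D convolutions (kernels
3/5/7, 8 filters each, ReLU), concatenates them, and merges with a 1×1
projection of the block input through a highway gate
g·H(x) + (1−g)·P(x), gate bias initialized to −1 so blocks start as
near-pass-throughs.  Global average pooling and a sigmoid head give the
probability; ~4.4k parameters.  Forward and backward passes are written
in NumPy (verified against finite differences) with Adam
(lr 3e-3, batch 256), weighted cross-entropy (positive weight
n_neg/n_pos), and early stopping on validation AUC (patience 6; ties keep
the later, more confident weights).  Every window of a truncated case
series is a positive (the series is the label); a horizon-limited
labeling is available behind the sample-construction switch.  Training
subsamples at most 25 windows per patient for speed; prediction always
scores every hour.  All randomness flows from a single seed, so training
is bit-reproducible.

**Calibration.**  Platt scaling (a·logit(p) + b through a logistic fit)
on the calibration split; monotone whenever a > 0, hence rank- and
AUC-preserving.  A degenerate (a ≤ 0) fit falls back to identity.  The
0–100 score is 100× the calibrated probability; the published alarm
semantics (scores above 70 = high risk) is kept as the default threshold
constant, but operating thresholds are re-derived per run from the ROC
(the published 56/70/72 are artifacts of the original training data).

## Evaluation

Patient-level scores: a case counts as detected if any pre-onset hourly
score exceeds the threshold; a control counts as a false positive if any
hour does.  Window-level AUC is also reported, since patient- and
window-level accounting differ under class imbalance.  The knee point is
the ROC vertex minimizing Euclidean distance to (0, 1) (ties to higher
sensitivity; Youden's J available by flag).  The 80%-sensitivity point is
the highest threshold reaching the target.  Test metrics are summarized
as mean ± SD over 100 seeded 80% subsamples without replacement;
single-class subsamples are redrawn and counted.  Early detection is the
fraction of cases whose first alarm precedes onset by at least 12 h;
cases that never alarm are misses.  Per-stage breakdown shares the
control pool (one specificity, per-stage sensitivities and LRs).

Null benchmarks permute labels at the patient level and average the
held-out AUC over three permutations: with ~3% prevalence a single
permutation's AUC has Monte-Carlo scatter of order 0.1, wider than the
chance band the check asserts, and averaging restores the resolution
without loosening the band.

## Numerical conventions

Strict inequalities at rule boundaries (oliguria `<`, alarm `<`,
duration `>`); anuria at ≤ 1e-9; stage-2 band inclusive at 300%; gap
limits strict.  Degenerate inputs raise `ValueError` with the offending
field.  The scale of the problem in tests — 2,000 patients for the
benchmark, 500/1,000 for label recovery, 1,000 stays for conservation —
keeps the whole suite desk-scale while leaving every property at the
sample size where its statistics are meaningful.

## Known limitations

Trailing hours after the last urine record are zero-filled and flagged
imputed; a trailing gap over 9 h excludes the stay, and shorter tails
cannot complete an anuria clause alone, but a tail adjacent to true
oliguria can extend a run harmlessly (onset anchors to run start +
duration).  The deep model's evaluation level (patient vs window) is
reported at both levels rather than resolved.  The single-feature
published thresholds are constants from a different data distribution
and are not refitted by default.  Real-data performance claims are out
of scope by construction.
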