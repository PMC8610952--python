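# akiwatch

Continuous, urine-output-based early warning for **severe acute kidney
injury (AKI, AKIN stage 2/3)** in ICU patients.

Severe AKI is diagnosed jointly from serum creatinine (sCr) and urine
output (UO): stage 2 requires an sCr rise to 200–300% of baseline together
with UO < 0.5 ml/kg/h for more than 12 h; stage 3 requires sCr > 300% of
baseline (or ≥ 4.0 mg/dl with an acute rise ≥ 0.5 mg/dl) together with
UO < 0.3 ml/kg/h for more than 24 h or anuria for more than 12 h.  By the
time these criteria complete, the kidney insult is hours old.  This package
implements and evaluates two predictors that score the risk of an upcoming
stage-2/3 episode *hours before the criteria are met*, using nothing but
the charted urine output normalized to ideal body weight (Devine's
formula):

* **Sliding-window logistic regression** — for window lengths
  w ∈ {2, …, 12} h, the feature
  f_w(t) = min_s mean(UO[s, s+w)) over all windows ending by prediction
  hour t; an 11-feature maximum-likelihood logistic model, and a
  single-feature threshold rule (alarm when f₇ < 0.372 ml/kg/h, the
  published operating threshold).
* **Convolutional risk score** — a compact 1-D CNN (parallel kernels
  3/5/7, two stacked blocks with highway gates, ~4.4k parameters,
  implemented in NumPy) mapping the last 12 h of UO to a calibrated 0–100
  score, updated hourly; a score at hour t refers to onset risk from
  t + 6 h onward.  Case series are truncated 6 h before onset so every
  training label respects that lead.

Because the clinical source databases require credentialed access, the
package ships a **synthetic cohort generator** that reproduces the
statistical structure the analysis needs — irregular nurse charting with
gaps, ~3% stage-2/3 prevalence, jointly consistent UO/sCr case
trajectories with known onset, controls with transient non-qualifying
oliguria — so the entire pipeline is testable end to end.  Evaluation
follows the early-warning-score protocol: patient-disjoint 60/10/20/10
train/validation/test/calibration splits, ROC analysis with two operating
points (80% sensitivity and the ROC knee), likelihood ratios
LR+ = sens/(1−spec) and LR− = (1−sens)/spec, and the fraction of cases
detected at least 12 h before onset.

## Worked example

The numbered scripts under `analysis/` run the study on a synthetic
cohort (1,200 patients here; tables land under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_hourly.py
python analysis/03_label_episodes.py
python analysis/04_logistic_models.py
python analysis/05_deep_model.py
python analysis/06_operating_points.py
```

which prints, stage by stage:

```
wrote 1200 stays to results/cohort
injected stage-2/3 cases: 31 (2.6%, target 3%)
31 stage-2/3 episodes among 1200 stays
sanity: 100.0% of injected cases recovered with matching stage
multi-feature logistic: test AUC 0.969 (resampled 0.968 +/- 0.007)
cnn (4369 parameters, 21 epochs): test AUC 0.993 (resampled 0.993 +/- 0.003)
  knee point: sens 100.0% spec 98.3% at score 11.8
  early detection (>= 12 h before onset): 57.1% of cases
```

The labeler recovers every injected episode (the generator and the
labeler are adversarially matched — controls may dip below 0.5 ml/kg/h,
but never long enough to qualify).  Both models separate cases from
controls almost perfectly here: the synthetic signal is constructed to be
detectable, so these numbers demonstrate that the machinery works, not
how it would fare on real ICU data.  "Early detection" counts test cases
whose first alarm at the knee threshold precedes criteria completion by
at least 12 h.

The library surface mirrors the stages: `akiwatch.synthetic`
(cohort generation), `akiwatch.preprocess` (hourly resampling, UO
redistribution imputation, sCr forward-fill, exclusion screening),
`akiwatch.labeling` (AKIN staging and onset timing),
`akiwatch.features` / `akiwatch.cnn` (the two models),
`akiwatch.evaluate` (ROC, operating points, likelihood ratios, early
detection) and `akiwatch.pipeline.run_pipeline` (the driver; accepts a
flat `key = value` config file).

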