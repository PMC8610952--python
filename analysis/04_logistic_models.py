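#!/usr/bin/env python
"""Fit and evaluate the sliding-window logistic models.

Multi-feature variant: 11 minimum-moving-average features (windows 2-12 h),
one randomly sampled prediction hour per patient, plain maximum-likelihood
logistic regression.  Single-feature variant: the published fixed rule
(7-h window, alarm below 0.372 ml/kg/h).  Writes the model report and the
fitted coefficients under results/.
"""

import argparse
import json
from pathlib import Path

from akiwatch import pipeline

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results/logistic"))
parser.add_argument("--seed", type=int, default=17)
args = parser.parse_args()

cfg = pipeline.PipelineConfig()
cfg.input_dir = str(args.cohort_dir)
cfg.split_seed = args.seed
cfg.models = ("logistic_multi", "logistic_single")
report = pipeline.run_pipeline(cfg, out_dir=args.out_dir)

lm, ls = report["logistic_multi"], report["logistic_single"]
print(f"multi-feature logistic: test AUC {lm['auc']:.3f} "
      f"(resampled {lm['auc_mean']:.3f} +/- {lm['auc_sd']:.3f})")
print(f"  knee point: sens {100 * lm['knee']['sensitivity']:.1f}% "
      f"spec {100 * lm['knee']['specificity']:.1f}%")
print(f"single-feature rule (w={ls['window_w']}, thr {ls['threshold']} ml/kg/h): "
      f"AUC {ls['auc']:.3f}, sens {100 * ls['sensitivity']:.1f}%, spec {100 * ls['specificity']:.1f}%")
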