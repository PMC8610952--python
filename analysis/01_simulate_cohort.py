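#!/usr/bin/env python
"""Generate the synthetic ICU cohort and write its long-format tables.

Emits patients.csv / urine_output.csv / creatinine.csv (the pipeline's
input contract) plus truth.csv, the generator-only ground truth that no
downstream stage reads.  Prints the realized case prevalence.
"""

import argparse
from pathlib import Path

from akiwatch.synthetic import CohortConfig, generate_cohort, write_cohort_csvs

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--n-patients", type=int, default=1200)
parser.add_argument("--prevalence", type=float, default=0.03)
parser.add_argument("--seed", type=int, default=11)
parser.add_argument("--out-dir", type=Path, default=Path("results/cohort"))
args = parser.parse_args()

cfg = CohortConfig(n_patients=args.n_patients, prevalence=args.prevalence, seed=args.seed)
stays = generate_cohort(cfg)
write_cohort_csvs(stays, args.out_dir)

n_cases = sum(s.truth_label == "case" for s in stays)
print(f"wrote {len(stays)} stays to {args.out_dir}")
print(f"injected stage-2/3 cases: {n_cases} ({100 * n_cases / len(stays):.1f}%, target {100 * cfg.prevalence:.0f}%)")
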