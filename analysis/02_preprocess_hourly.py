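#!/usr/bin/env python
"""Resample the raw cohort onto the hourly grid and screen exclusions.

Writes the tidy hourly series (ml/kg/h, mg/dl, imputation flags) and the
per-patient exclusion report; prints the exclusion waterfall.
"""

import argparse
from pathlib import Path

import pandas as pd

from akiwatch import preprocess
from akiwatch.synthetic import read_cohort_csvs

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

stays = read_cohort_csvs(args.cohort_dir)
series_list, flags_list = [], []
for stay in stays:
    series, flags = preprocess.preprocess_stay(stay)
    series_list.append(series)
    flags_list.append(flags)

kept, reports = preprocess.apply_exclusions(flags_list)
args.out_dir.mkdir(parents=True, exist_ok=True)
preprocess.series_to_frame(series_list).to_csv(args.out_dir / "hourly_series.csv", index=False)
pd.DataFrame(
    [{"patient_id": r.patient_id, "excluded": r.excluded, "reasons": ";".join(r.reasons)}
     for r in reports]
).to_csv(args.out_dir / "exclusions.csv", index=False)

print(f"{len(stays)} stays in, {len(kept)} kept")
by_reason = {}
for r in reports:
    for reason in r.reasons:
        by_reason[reason] = by_reason.get(reason, 0) + 1
for reason, count in sorted(by_reason.items()):
    print(f"  excluded ({reason}): {count}")
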