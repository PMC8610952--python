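#!/usr/bin/env python
"""Summarize both models as an operating-point table.

Reads the reports written by 04_logistic_models.py and 05_deep_model.py
and prints the working-point table (auROC, sensitivity, specificity,
LR+, LR-) for the 80%-sensitivity point and the knee point.
"""

import argparse
import json
from pathlib import Path

from akiwatch.evaluate import format_operating_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--results-dir", type=Path, default=Path("results"))
args = parser.parse_args()

rows = []
for model_name, sub in (("logistic (multi)", "logistic/report.json"),
                        ("deep learning", "deep/report.json")):
    path = args.results_dir / sub
    if not path.exists():
        print(f"missing {path} - run the fitting scripts first")
        continue
    report = json.loads(path.read_text())
    block = report.get("cnn") or report.get("logistic_multi")
    for kind, label in (("sens80", "sensitivity = 80%"), ("knee", "knee-point")):
        op = block[kind]
        rows.append({"model": model_name, "working_point": label,
                     "auroc": block["auc"], "sensitivity": op["sensitivity"],
                     "specificity": op["specificity"], "lr_pos": min(op["lr_pos"], 999.0),
                     "lr_neg": op["lr_neg"]})

table = format_operating_table(rows)
print(table)
(args.results_dir / "operating_points.txt").write_text(table + "\n")
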