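"""Splits, ROC analysis, operating points, likelihood ratios, early detection.

Evaluation follows the usual early-warning-score protocol: the cohort is
partitioned by patient into train/validation/test/calibration (60/10/20/10,
so no patient leaks across splits), the score is assessed by ROC analysis,
and two operating points are reported — the threshold achieving 80%
sensitivity, and the knee-point (the ROC vertex closest to the ideal
top-left corner).  Likelihood ratios summarise each point:
LR+ = sens / (1 - spec), LR- = (1 - sens) / spec.  Early detection is the
fraction of cases whose first alarm precedes onset by at least the required
lead (12 h by default).  Test-set metrics are reported as mean +/- SD over
seeded random subsamples of the test pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

SPLIT_NAMES = ("train", "validation", "test", "calibration")
SPLIT_PROPORTIONS = (0.6, 0.1, 0.2, 0.1)
DEFAULT_LEAD_H = 12
DEFAULT_TARGET_SENSITIVITY = 0.80


def assign_splits(patient_ids, seed: int, proportions=SPLIT_PROPORTIONS) -> Dict[str, str]:
    """Seeded 60/10/20/10 patient-level partition (largest-remainder counts,
    every count within one patient of its target)."""
    ids = list(patient_ids)
    if len(ids) < 10:
        raise ValueError(f"need at least 10 patients to split, got {len(ids)}")
    if not math.isclose(sum(proportions), 1.0, abs_tol=1e-9):
        raise ValueError("split proportions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n = len(ids)
    exact = [p * n for p in proportions]
    counts = [int(math.floor(e)) for e in exact]
    remainders = sorted(range(len(exact)), key=lambda i: exact[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[remainders[i % len(counts)]] += 1
    assignment = {}
    pos = 0
    for name, c in zip(SPLIT_NAMES, counts):
        for j in order[pos : pos + c]:
            assignment[ids[j]] = name
        pos += c
    return assignment


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_curve_and_auc(scores, labels) -> RocResult:
    """ROC vertices and AUC (tie-corrected Mann-Whitney normalization)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    return RocResult(fpr, tpr, thr, float(roc_auc_score(y, scores)))


def likelihood_ratios(sensitivity: float, specificity: float):
    """(LR+, LR-).  LR+ is infinite at specificity 1; LR- at specificity 0."""
    lr_pos = sensitivity / (1.0 - specificity) if specificity < 1.0 else math.inf
    lr_neg = (1.0 - sensitivity) / specificity if specificity > 0.0 else math.inf
    return lr_pos, lr_neg


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    kind: str  # fixed_sensitivity_80 | knee

    @classmethod
    def at(cls, threshold, sens, spec, kind) -> "OperatingPoint":
        lp, ln = likelihood_ratios(sens, spec)
        return cls(float(threshold), float(sens), float(spec), lp, ln, kind)


def operating_point_at_sensitivity(roc: RocResult, target: float = DEFAULT_TARGET_SENSITIVITY) -> OperatingPoint:
    """First ROC vertex reaching the target sensitivity (max specificity
    subject to sens >= target; sklearn orders thresholds descending)."""
    idx = int(np.argmax(roc.tpr >= target))
    return OperatingPoint.at(roc.thresholds[idx], roc.tpr[idx], 1.0 - roc.fpr[idx], "fixed_sensitivity_80")


def knee_point(roc: RocResult, method: str = "distance") -> OperatingPoint:
    """ROC vertex closest to (FPR 0, TPR 1); ties go to higher sensitivity.
    ``method="youden"`` maximizes sens + spec - 1 instead."""
    if method == "distance":
        crit = np.sqrt(roc.fpr**2 + (1.0 - roc.tpr) ** 2)
        best = np.min(crit)
        tied = np.flatnonzero(crit <= best + 1e-12)
    elif method == "youden":
        crit = roc.tpr - roc.fpr
        best = np.max(crit)
        tied = np.flatnonzero(crit >= best - 1e-12)
    else:
        raise ValueError(f"unknown knee method {method!r}")
    idx = int(tied[np.argmax(roc.tpr[tied])])
    return OperatingPoint.at(roc.thresholds[idx], roc.tpr[idx], 1.0 - roc.fpr[idx], "knee")


def early_detection_fraction(first_alarm_hours, onset_hours, lead: int = DEFAULT_LEAD_H) -> float:
    """Fraction of cases whose first alarm comes at least ``lead`` hours
    before onset; cases that never alarm count as misses."""
    onset_hours = list(onset_hours)
    if not onset_hours:
        raise ValueError("no cases with onset hours")
    hits = 0
    for alarm, onset in zip(first_alarm_hours, onset_hours):
        if alarm is not None and alarm <= onset - lead:
            hits += 1
    return hits / len(onset_hours)


def resampled_performance(scores, labels, n_resamples: int = 100, frac: float = 0.8,
                          seed: int = 0, target_sensitivity: float = DEFAULT_TARGET_SENSITIVITY):
    """Mean +/- SD of AUC and operating-point metrics over seeded random
    subsamples (without replacement) of the evaluation pool.  Single-class
    subsamples are redrawn; the redraw count is reported."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation pool needs both classes")
    rng = np.random.default_rng(seed)
    n_take = max(2, int(round(frac * len(y))))
    metrics = {k: [] for k in ("auc", "knee_sensitivity", "knee_specificity",
                               "sens80_specificity")}
    redraws = 0
    for _ in range(n_resamples):
        for _attempt in range(1000):
            idx = rng.choice(len(y), size=n_take, replace=False)
            if len(np.unique(y[idx])) > 1:
                break
            redraws += 1
        roc = roc_curve_and_auc(scores[idx], y[idx])
        knee = knee_point(roc)
        s80 = operating_point_at_sensitivity(roc, target_sensitivity)
        metrics["auc"].append(roc.auc)
        metrics["knee_sensitivity"].append(knee.sensitivity)
        metrics["knee_specificity"].append(knee.specificity)
        metrics["sens80_specificity"].append(s80.specificity)
    out = {}
    for k, vals in metrics.items():
        arr = np.asarray(vals)
        out[f"{k}_mean"] = float(arr.mean())
        out[f"{k}_sd"] = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    out["n_resamples"] = n_resamples
    out["n_redraws"] = redraws
    return out


def per_stage_breakdown(scores, labels, stages, threshold: float) -> Dict[int, dict]:
    """Sensitivity/LRs per AKIN stage at a fixed alarm threshold; the control
    pool (hence specificity) is shared by both stages.  Also reports the
    stage-restricted AUC (stage's cases vs all controls)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    stages = np.asarray([s if s is not None else 0 for s in stages])
    controls = y == 0
    if not controls.any():
        raise ValueError("no controls in the evaluation pool")
    specificity = float(np.mean(scores[controls] <= threshold))
    out = {}
    for stage in (2, 3):
        mask = (y == 1) & (stages == stage)
        if not mask.any():
            continue
        sens = float(np.mean(scores[mask] > threshold))
        lp, ln = likelihood_ratios(sens, specificity)
        sub = mask | controls
        out[stage] = {
            "sensitivity": sens,
            "specificity": specificity,
            "lr_pos": lp,
            "lr_neg": ln,
            "auc": float(roc_auc_score(y[sub], scores[sub])),
            "n_cases": int(mask.sum()),
        }
    return out


def format_operating_table(rows) -> str:
    """Plain-text operating-point table (working point, auROC, sensitivity,
    specificity, LR+, LR-).  ``rows`` are dicts with those keys; LRs are
    shown at 2 decimals, the rest as percentages or 2-dp fractions."""
    header = f"{'model':<22}{'working point':<18}{'auROC':>7}{'sens':>8}{'spec':>8}{'LR+':>8}{'LR-':>8}"
    lines = [header, "-" * len(header)]
    for r in rows:
        lines.append(
            f"{r['model']:<22}{r['working_point']:<18}"
            f"{r['auroc']:>7.2f}{100 * r['sensitivity']:>7.1f}%{100 * r['specificity']:>7.1f}%"
            f"{r['lr_pos']:>8.2f}{r['lr_neg']:>8.2f}"
        )
    return "\n".join(lines)


def first_alarm_hour(score_frame, threshold: float) -> Optional[int]:
    """First hour a stay's score exceeds the alarm threshold, or None."""
    hit = score_frame.loc[score_frame["score"] > threshold, "hour"]
    return int(hit.iloc[0]) if len(hit) else None
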