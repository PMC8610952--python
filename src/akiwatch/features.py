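"""Sliding-window minimum-moving-average features and logistic risk models.

The feature set summarises how deep and how sustained a patient's worst
oliguric episode has been so far: for each window length w in [2, 12] hours,
take the moving average of the hourly urine flow (ml/kg/h) from admission up
to the prediction hour and keep its minimum.  Eleven numbers per prediction
hour.  A prediction hour t uses hours [0, t) only, and the earliest eligible
hour is t = 12 (one full 12-h window).

Two logistic variants mirror the study design: a multi-feature model fitted
on all 11 features (plain maximum likelihood), and a single-feature
threshold rule ("alarm when the w-hour minimum moving average falls below
theta").  The published single-feature thresholds (e.g. 0.372 ml/kg/h at
w = 7) are shipped as fixed rules; thresholds can also be re-fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.linear_model import LogisticRegression

WINDOW_RANGE = range(2, 13)
MIN_PREDICTION_HOUR = 12

#: published single-feature thresholds (ml/kg/h) per window length
PUBLISHED_THRESHOLDS: Dict[int, float] = {
    2: 0.251, 3: 0.288, 4: 0.311, 5: 0.341, 6: 0.362, 7: 0.372,
    8: 0.407, 9: 0.427, 10: 0.457, 11: 0.471, 12: 0.487,
}


@dataclass(frozen=True)
class SingleFeatureRule:
    window_w: int = 7
    threshold_mlkg_h: float = PUBLISHED_THRESHOLDS[7]

    def __post_init__(self):
        if self.window_w not in WINDOW_RANGE:
            raise ValueError(f"window_w must be in [2, 12], got {self.window_w}")
        if self.threshold_mlkg_h <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class FeatureVector:
    patient_id: str
    prediction_hour: int
    features: Dict[int, float]  # window length -> min moving average
    label: str  # case | control


def min_moving_average(uo, w: int) -> float:
    """Minimum over all length-``w`` contiguous windows of the mean flow."""
    uo = np.asarray(uo, dtype=float)
    if w < 1:
        raise ValueError(f"window length must be >= 1, got {w}")
    if len(uo) < w:
        raise ValueError(f"series of length {len(uo)} shorter than window {w}")
    return float(sliding_window_view(uo, w).mean(axis=1).min())


def extract_features(uo, t: int, patient_id: str = "", label: str = "control") -> FeatureVector:
    """The 11 features at prediction hour ``t``, computed over hours [0, t)."""
    uo = np.asarray(uo, dtype=float)
    if t < MIN_PREDICTION_HOUR:
        raise ValueError(f"prediction hour must be >= {MIN_PREDICTION_HOUR}, got {t}")
    if len(uo) < t:
        raise ValueError(f"series has only {len(uo)} hours, needs {t}")
    u = uo[:t]
    return FeatureVector(patient_id, t, {w: min_moving_average(u, w) for w in WINDOW_RANGE}, label)


def feature_table(series_list, labels: Dict[str, str]) -> pd.DataFrame:
    """All eligible (patient, hour) feature rows.

    Controls contribute a row at every hour from 12 to discharge; cases
    contribute every hour of their (already truncated) series.
    """
    rows = []
    for s in series_list:
        lab = labels.get(s.patient_id, "control")
        uo = np.asarray(s.uo_mlkg_h, dtype=float)
        n = len(uo)
        if n < MIN_PREDICTION_HOUR:
            continue
        # prefix-min of window means: f[w] at hour t is the running minimum of
        # all length-w window means whose window ends by t (same value as
        # extract_features, linear instead of quadratic in stay length)
        prefix = {}
        for w in WINDOW_RANGE:
            means = sliding_window_view(uo, w).mean(axis=1)
            prefix[w] = np.minimum.accumulate(means)
        for t in range(MIN_PREDICTION_HOUR, n + 1):
            row = {"patient_id": s.patient_id, "hour": t, "label": lab}
            row.update({f"f{w}": prefix[w][t - w] for w in WINDOW_RANGE})
            rows.append(row)
    return pd.DataFrame(rows)


def sample_one_per_patient(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """One uniformly chosen feature row per patient (independence across
    samples in the logistic fit); deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    picks = []
    for _, group in table.groupby("patient_id", sort=True):
        picks.append(group.iloc[int(rng.integers(0, len(group)))])
    return pd.DataFrame(picks).reset_index(drop=True)


FEATURE_COLUMNS = [f"f{w}" for w in WINDOW_RANGE]


class MultiFeatureLogistic:
    """Unpenalized logistic regression on the 11 features.

    ``regularization=None`` is the default (plain MLE); pass a positive
    float C to enable L2 (useful on perfectly separable toy data).
    """

    def __init__(self, regularization=None, max_iter: int = 5000):
        C = np.inf if regularization is None else float(regularization)
        self._lr = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter)

    def fit(self, table: pd.DataFrame) -> "MultiFeatureLogistic":
        y = (table["label"] == "case").to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both cases and controls")
        self._lr.fit(table[FEATURE_COLUMNS].to_numpy(), y)
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self._lr.predict_proba(table[FEATURE_COLUMNS].to_numpy())[:, 1]

    @property
    def coefficients(self) -> Dict[str, float]:
        out = {c: float(v) for c, v in zip(FEATURE_COLUMNS, self._lr.coef_[0])}
        out["intercept"] = float(self._lr.intercept_[0])
        return out


def fit_multifeature_logistic(table: pd.DataFrame, regularization=None) -> MultiFeatureLogistic:
    return MultiFeatureLogistic(regularization=regularization).fit(table)


def apply_single_feature_rule(fv, rule: SingleFeatureRule) -> bool:
    """Alarm iff the w-hour minimum moving average is strictly below the
    threshold.  Accepts a FeatureVector or a feature-table row."""
    if isinstance(fv, FeatureVector):
        value = fv.features[rule.window_w]
    else:
        value = float(fv[f"f{rule.window_w}"])
    return value < rule.threshold_mlkg_h
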