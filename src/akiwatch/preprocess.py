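"""Hourly resampling, imputation and exclusion screening for raw ICU records.

Raw urine-output (UO) and serum-creatinine (sCr) charting in the ICU is
irregular: nurses enter cumulative urine volumes at variable intervals and
creatinine is a lab draw every several hours to days.  This module turns one
ICU stay's raw records into an hourly series:

* UO volumes covering a multi-hour unrecorded interval are redistributed
  uniformly over the hours they span (conserving total volume);
* sCr values are dragged forward to the next measurement;
* UO flow is normalized to ideal body weight (Devine's formula), giving
  ml/kg/h, the unit in which oliguria thresholds are defined;
* stays that violate the cohort's data-quality rules (short stay, long
  charting gaps, low baseline creatinine, dialysis, low-volume center,
  community-acquired AKI) are flagged for exclusion.

Hours are 0-based half-open bins: hour ``h`` covers ``[h, h+1)`` since
admission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CM_PER_INCH = 2.54
#: unrecorded-UO interval longer than this excludes the stay ("more than 9 h")
UO_GAP_LIMIT_H = 9.0
#: sCr gap longer than this excludes the stay ("more than 4 days")
SCR_GAP_LIMIT_H = 96.0
MIN_LOS_H = 24.0
BASELINE_SCR_FLOOR = 0.5
MIN_CENTER_ADMISSIONS = 50
#: stage-2/3 criteria met within the first N hours count as community-acquired
COMMUNITY_ACQUIRED_HORIZON_H = 12

EXCLUSION_REASONS = (
    "los_lt_24h",
    "baseline_scr_lt_0.5",
    "community_acquired_aki",
    "dialysis",
    "uo_gap_gt_9h",
    "scr_gap_gt_4d",
    "low_volume_center",
)


def compute_ibw(sex: str, height_cm: float) -> float:
    """Ideal body weight in kg by Devine's formula.

    male: 50 kg + 2.3 kg per inch over 60 in; female: 45.5 kg + 2.3 kg/in.
    Heights below 60 in return the base weight (the formula is undefined
    there and a decreasing extrapolation would blow up the ml/kg/h flow).
    """
    if height_cm <= 0:
        raise ValueError(f"height_cm must be positive, got {height_cm}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    base = 50.0 if sex == "male" else 45.5
    inches_over = height_cm / CM_PER_INCH - 60.0
    return base + 2.3 * max(0.0, inches_over)


def _as_hours(t, admit) -> float:
    """Timestamp or numeric -> float hours since admission."""
    if isinstance(t, (pd.Timestamp, np.datetime64)):
        return (pd.Timestamp(t) - pd.Timestamp(admit)) / pd.Timedelta(hours=1)
    return float(t) - (float(admit) if not isinstance(admit, (pd.Timestamp, np.datetime64)) else 0.0)


def stay_hours(admit, discharge) -> int:
    los = _as_hours(discharge, admit)
    if los <= 0:
        raise ValueError("discharge must be after admission")
    return int(math.ceil(los - 1e-9))


def resample_uo_hourly(uo_records, admit, discharge):
    """Redistribute charted urine volumes onto the hourly grid.

    Each record ``(t_i, v_i)`` covers the unrecorded interval since the
    previous record (or admission); its volume is spread uniformly over that
    interval and accumulated into the hour bins it overlaps, prorating
    partial bins, so total volume is conserved.

    Returns ``(uo_ml, imputed, gap_exceeded)``: hourly volumes, a per-hour
    flag marking hours whose value was shared across a multi-hour interval,
    and a stay-level flag set when any unrecorded interval (including the
    tail to discharge) exceeds 9 h.  Long gaps are still filled — exclusion,
    not silent truncation, is the downstream consequence.
    """
    n_hours = stay_hours(admit, discharge)
    los = _as_hours(discharge, admit)
    uo = np.zeros(n_hours)
    imputed = np.zeros(n_hours, dtype=bool)
    gap_exceeded = False

    t_prev = 0.0
    for t, v in uo_records:
        th = _as_hours(t, admit)
        if v < 0:
            raise ValueError(f"negative urine volume {v}")
        if th < t_prev - 1e-9:
            raise ValueError("urine-output records must be sorted by time")
        gap = th - t_prev
        if gap <= 1e-12:
            # coincident record: assign to the containing hour
            b = min(n_hours - 1, int(th))
            uo[b] += v
            continue
        if gap > UO_GAP_LIMIT_H + 1e-9:
            gap_exceeded = True
        rate = v / gap
        b0 = max(0, int(math.floor(t_prev)))
        b1 = min(n_hours, int(math.ceil(th - 1e-12)))
        for b in range(b0, b1):
            overlap = min(th, b + 1) - max(t_prev, b)
            if overlap > 0:
                uo[b] += rate * overlap
                if gap > 1.0 + 1e-9:
                    imputed[b] = True
        t_prev = th

    if los - t_prev > UO_GAP_LIMIT_H + 1e-9:
        gap_exceeded = True
    # hours after the last record carry no information; they stay 0 and
    # are flagged imputed so the labeler's anuria clause can be audited
    tail0 = int(math.ceil(t_prev - 1e-12))
    if tail0 < n_hours:
        imputed[tail0:] = True
    return uo, imputed, gap_exceeded


def forward_fill_scr(scr_records, admit, discharge):
    """Drag each creatinine value forward to the next measurement.

    Hours before the first draw are back-filled from it (flagged imputed).
    Returns ``(scr, imputed, gap_exceeded)``; ``gap_exceeded`` is set when
    any inter-measurement gap (or lead-in/tail) exceeds 4 days, or when the
    stay has no creatinine at all.
    """
    n_hours = stay_hours(admit, discharge)
    los = _as_hours(discharge, admit)
    scr = np.full(n_hours, np.nan)
    imputed = np.ones(n_hours, dtype=bool)
    if not scr_records:
        return scr, imputed, True

    times, values = [], []
    for t, v in scr_records:
        th = _as_hours(t, admit)
        if v <= 0:
            raise ValueError(f"creatinine must be positive, got {v}")
        if times and th < times[-1] - 1e-9:
            raise ValueError("creatinine records must be sorted by time")
        times.append(th)
        values.append(float(v))

    gap_exceeded = times[0] > SCR_GAP_LIMIT_H + 1e-9
    for a, b in zip(times, times[1:]):
        if b - a > SCR_GAP_LIMIT_H + 1e-9:
            gap_exceeded = True
    if los - times[-1] > SCR_GAP_LIMIT_H + 1e-9:
        gap_exceeded = True

    hours = [min(n_hours - 1, max(0, int(th))) for th in times]
    # back-fill lead-in
    scr[: hours[0]] = values[0]
    for i, (h, v) in enumerate(zip(hours, values)):
        h_next = hours[i + 1] if i + 1 < len(hours) else n_hours
        scr[h:max(h + 1, h_next)] = v
        imputed[h] = False
    return scr, imputed, gap_exceeded


def baseline_scr(scr_values_per_stay) -> float:
    """Baseline creatinine: the lowest observed ICU value across all of a
    patient's stays (the datasets carry no pre-admission baseline)."""
    lows = []
    for vals in scr_values_per_stay:
        arr = np.asarray(list(vals), dtype=float)
        if arr.size and not np.all(np.isnan(arr)):
            lows.append(np.nanmin(arr))
    if not lows:
        raise ValueError("no creatinine values to compute a baseline from")
    return float(min(lows))


@dataclass
class HourlySeries:
    """One stay on the hourly grid (hour h covers [h, h+1) since admission)."""

    patient_id: str
    uo_ml: np.ndarray
    uo_mlkg_h: np.ndarray
    scr_mg_dl: np.ndarray
    uo_imputed: np.ndarray
    scr_imputed: np.ndarray
    ibw_kg: float

    def __len__(self) -> int:
        return len(self.uo_ml)

    def sliced(self, n_hours: int) -> "HourlySeries":
        return HourlySeries(
            patient_id=self.patient_id,
            uo_ml=self.uo_ml[:n_hours].copy(),
            uo_mlkg_h=self.uo_mlkg_h[:n_hours].copy(),
            scr_mg_dl=self.scr_mg_dl[:n_hours].copy(),
            uo_imputed=self.uo_imputed[:n_hours].copy(),
            scr_imputed=self.scr_imputed[:n_hours].copy(),
            ibw_kg=self.ibw_kg,
        )


@dataclass
class StayFlags:
    """Stay-level facts that feed the exclusion screen."""

    patient_id: str
    center_id: str
    los_hours: float
    baseline_scr: float
    dialysis: bool = False
    uo_gap_exceeded: bool = False
    scr_gap_exceeded: bool = False
    community_acquired: bool = False


@dataclass
class ExclusionReport:
    patient_id: str
    excluded: bool
    reasons: list = field(default_factory=list)


def preprocess_stay(stay) -> tuple:
    """RawStay -> (HourlySeries, StayFlags).  Baseline sCr is the stay's own
    minimum; callers with multi-admission patients should override it via
    :func:`baseline_scr` across stays."""
    ibw = compute_ibw(stay.sex, stay.height_cm)
    uo_ml, uo_imp, uo_gap = resample_uo_hourly(stay.uo_records, stay.admit_time, stay.discharge_time)
    scr, scr_imp, scr_gap = forward_fill_scr(stay.scr_records, stay.admit_time, stay.discharge_time)
    series = HourlySeries(
        patient_id=stay.patient_id,
        uo_ml=uo_ml,
        uo_mlkg_h=uo_ml / ibw,
        scr_mg_dl=scr,
        uo_imputed=uo_imp,
        scr_imputed=scr_imp,
        ibw_kg=ibw,
    )
    base = baseline_scr([scr[~np.isnan(scr)]]) if not np.all(np.isnan(scr)) else np.nan
    flags = StayFlags(
        patient_id=stay.patient_id,
        center_id=stay.center_id,
        los_hours=_as_hours(stay.discharge_time, stay.admit_time),
        baseline_scr=base,
        dialysis=getattr(stay, "dialysis", False),
        uo_gap_exceeded=uo_gap,
        scr_gap_exceeded=scr_gap,
    )
    return series, flags


def apply_exclusions(flags_list, min_center_admissions: int = MIN_CENTER_ADMISSIONS):
    """Apply the cohort exclusion rules to a list of :class:`StayFlags`.

    Returns ``(kept_ids, reports)`` where every report lists *all* reasons
    that apply (the waterfall accounting elsewhere uses the first).
    """
    center_counts = {}
    for f in flags_list:
        center_counts[f.center_id] = center_counts.get(f.center_id, 0) + 1

    reports, kept = [], []
    for f in flags_list:
        reasons = []
        if f.los_hours < MIN_LOS_H:
            reasons.append("los_lt_24h")
        if np.isnan(f.baseline_scr) or f.baseline_scr < BASELINE_SCR_FLOOR:
            reasons.append("baseline_scr_lt_0.5")
        if f.community_acquired:
            reasons.append("community_acquired_aki")
        if f.dialysis:
            reasons.append("dialysis")
        if f.uo_gap_exceeded:
            reasons.append("uo_gap_gt_9h")
        if f.scr_gap_exceeded:
            reasons.append("scr_gap_gt_4d")
        if center_counts[f.center_id] < min_center_admissions:
            reasons.append("low_volume_center")
        excluded = bool(reasons)
        reports.append(ExclusionReport(f.patient_id, excluded, reasons))
        if not excluded:
            kept.append(f.patient_id)
    return kept, reports


def series_to_frame(series_list) -> pd.DataFrame:
    """Tidy hourly CSV contract: one row per (patient, hour)."""
    rows = []
    for s in series_list:
        for h in range(len(s)):
            rows.append(
                {
                    "patient_id": s.patient_id,
                    "hour": h,
                    "uo_mlkg_h": s.uo_mlkg_h[h],
                    "scr_mg_dl": s.scr_mg_dl[h],
                    "uo_imputed": bool(s.uo_imputed[h]),
                    "scr_imputed": bool(s.scr_imputed[h]),
                }
            )
    return pd.DataFrame(rows)
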