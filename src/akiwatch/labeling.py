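"""AKIN stage-2/3 episode detection from joint creatinine + urine-output criteria.

The study endpoint is an ICU-acquired AKIN stage 2 or 3 episode defined by
the *simultaneous* creatinine and urine-output clauses:

* stage 2 — sCr rise to 200–300% of baseline AND urine output
  < 0.5 ml/kg/h for a period > 12 h;
* stage 3 — sCr rise > 300% of baseline, or sCr ≥ 4.0 mg/dl with an acute
  rise ≥ 0.5 mg/dl (within a rolling 48-h window, the AKIN convention),
  AND urine output < 0.3 ml/kg/h for > 24 h or anuria for > 12 h.

Durations are strict ("> 12 h" needs 13 full oliguric hours).  Onset is
anchored at the hour the urine-output duration clause completes — the first
hour the diagnostic criteria are actually met.  The creatinine clause must
hold within the oliguria window or within a coupling window (default 24 h)
after its completion, tolerating lab-draw latency; the guidelines combine
the clauses without prescribing the coupling, so it is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .preprocess import HourlySeries

ANURIA_EPS = 1e-9
#: (threshold ml/kg/h, strict minimum duration in hours)
STAGE2_UO = (0.5, 12)
STAGE3_UO_LOW = (0.3, 24)
STAGE3_UO_ANURIA = (0.0, 12)
SCR_ABS_THRESHOLD = 4.0
SCR_ABS_RISE = 0.5
SCR_RISE_WINDOW_H = 48
DEFAULT_COUPLING_H = 24
#: earliest onset usable for prediction: 12-h lookback + 6-h lead + 1
MIN_PREDICTABLE_ONSET_H = 19
TRUNCATION_LEAD_H = 6


@dataclass(frozen=True)
class OliguriaWindow:
    start_hour: int
    end_hour: int  # half-open: hours start..end-1 are below threshold
    threshold_mlkg_h: float

    @property
    def duration(self) -> int:
        return self.end_hour - self.start_hour


@dataclass(frozen=True)
class AkiEpisode:
    patient_id: str
    stage: int
    onset_hour: int
    scr_criterion: str  # ratio_200_300 | ratio_gt_300 | abs_ge_4_with_rise_ge_0.5
    uo_criterion: str  # uo_lt_0.5_gt_12h | uo_lt_0.3_gt_24h | anuria_gt_12h


def find_oliguria_windows(uo_mlkg_h, threshold: float, min_duration: int):
    """Maximal runs of consecutive hours with flow below ``threshold``
    (at or below numerical zero for anuria, ``threshold == 0``), kept only
    when strictly longer than ``min_duration`` hours."""
    uo = np.asarray(uo_mlkg_h, dtype=float)
    if threshold <= ANURIA_EPS:
        below = uo <= ANURIA_EPS
    else:
        below = uo < threshold
    windows = []
    padded = np.concatenate(([False], below, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > min_duration:
            windows.append(OliguriaWindow(int(s), int(e), threshold))
    return windows


def _scr_stage2_band(scr: np.ndarray, baseline: float) -> np.ndarray:
    # 200–300% of baseline; the tie at exactly 300% belongs to stage 2
    with np.errstate(invalid="ignore"):
        return (scr >= 2.0 * baseline) & (scr <= 3.0 * baseline)


def _scr_stage3(scr: np.ndarray, baseline: float):
    with np.errstate(invalid="ignore"):
        ratio = scr > 3.0 * baseline
        rise = np.zeros(len(scr), dtype=bool)
        for h in range(len(scr)):
            lo = max(0, h - SCR_RISE_WINDOW_H)
            window = scr[lo : h + 1]
            if not np.all(np.isnan(window)):
                rise[h] = scr[h] - np.nanmin(window) >= SCR_ABS_RISE
        absolute = (scr >= SCR_ABS_THRESHOLD) & rise
    return ratio, absolute


def stage_episode(
    series: HourlySeries,
    baseline: float,
    coupling_hours: int = DEFAULT_COUPLING_H,
) -> Optional[AkiEpisode]:
    """Detect the first AKIN stage-2/3 episode of a stay, or ``None``.

    For each qualifying oliguria window the urine clause completes at
    ``start + min_duration`` (the 13th/25th oliguric hour).  The episode
    onset is the first hour at which both the completed urine clause and
    the creatinine clause hold, the creatinine clause being accepted
    anywhere inside the window or within ``coupling_hours`` after its end.
    The earliest onset wins; a tie between stages is assigned stage 3.
    """
    if baseline <= 0 or np.isnan(baseline):
        raise ValueError("baseline creatinine must be positive")
    uo = series.uo_mlkg_h
    scr = series.scr_mg_dl
    n = len(series)

    band2 = _scr_stage2_band(scr, baseline)
    ratio3, abs3 = _scr_stage3(scr, baseline)
    scr3 = ratio3 | abs3

    candidates = []  # (onset, stage_rank, episode); stage_rank: 0 for stage 3

    def scan(windows, min_dur, scr_mask, stage, uo_name):
        for w in windows:
            complete = w.start_hour + min_dur
            if complete >= n:
                continue
            hi = min(n, w.end_hour + coupling_hours)
            hit = np.flatnonzero(scr_mask[w.start_hour : hi])
            if hit.size == 0:
                continue
            first_scr = w.start_hour + int(hit[0])
            onset = max(complete, first_scr)
            if stage == 3:
                crit = "ratio_gt_300" if ratio3[first_scr] else "abs_ge_4_with_rise_ge_0.5"
            else:
                crit = "ratio_200_300"
            candidates.append(
                (onset, 0 if stage == 3 else 1,
                 AkiEpisode(series.patient_id, stage, onset, crit, uo_name))
            )

    scan(find_oliguria_windows(uo, *STAGE3_UO_LOW), STAGE3_UO_LOW[1], scr3, 3, "uo_lt_0.3_gt_24h")
    scan(find_oliguria_windows(uo, *STAGE3_UO_ANURIA), STAGE3_UO_ANURIA[1], scr3, 3, "anuria_gt_12h")
    scan(find_oliguria_windows(uo, *STAGE2_UO), STAGE2_UO[1], band2, 2, "uo_lt_0.5_gt_12h")

    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    return candidates[0][2]


def truncate_case_series(series: HourlySeries, onset_hour: int) -> HourlySeries:
    """Cut a case stay 6 h before onset so every prediction has a 6-h lead.

    Requires ``onset_hour ≥ 19`` (12-h feature lookback + 6-h lead + 1);
    earlier onsets leave no usable prediction window and the case is dropped
    by the caller.  Control series are never truncated — they are used from
    admission to discharge or death.
    """
    if onset_hour < MIN_PREDICTABLE_ONSET_H:
        raise ValueError(
            f"onset at hour {onset_hour} leaves no 12-h window with a 6-h lead "
            f"(need onset ≥ {MIN_PREDICTABLE_ONSET_H})"
        )
    return series.sliced(onset_hour - TRUNCATION_LEAD_H)
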