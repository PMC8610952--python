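"""Synthetic ICU cohort generator.

The real critical-care databases this kind of analysis draws on require
credentialed access; this module generates cohorts with the statistical
structure the pipeline assumes, so every downstream stage is testable end
to end:

* irregular urine-output charting — cumulative volumes entered at 1–8 h
  intervals (geometric-like gap lengths, truncated so default cohorts
  survive the 9-h exclusion);
* ~3% of patients carry an injected ICU-acquired AKIN stage-2/3 episode
  whose urine-output *and* creatinine trajectories jointly satisfy the
  staging criteria, with a known ground-truth onset hour;
* control stays may contain transient oliguria shorter than the AKIN
  durations, so the labeler is genuinely exercised;
* control minimum diuresis is right-skewed (lognormal hourly flow), and
  heights/sex ratios are in realistic adult ICU ranges (~63% male).

Ground truth (case/control, stage, onset) is written to a separate
``truth.csv`` that the pipeline proper never reads.

Design notes on injected cases
------------------------------
Onset is defined as the hour the urine-output duration clause completes,
so the oliguric run is placed to end its qualifying duration exactly at
the requested onset.  For stage 3 the creatinine trajectory jumps from
below 200% of baseline directly above 300% between consecutive lab draws
— forward-filled hourly creatinine then never visits the stage-2 band, so
the labeler cannot emit an earlier stage-2 episode during the (longer)
stage-3 oliguric run.  A lab draw is forced shortly before onset so the
creatinine clause is visible to the labeler by then despite sparse
sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import compute_ibw

_BASE_TIME = pd.Timestamp("2019-01-01 00:00:00")


@dataclass
class CohortConfig:
    n_patients: int = 2000
    prevalence: float = 0.03
    n_centers: int = 4
    #: geometric success prob for inter-record gap (hours); mean gap ~ 1/p
    uo_gap_geometric_p: float = 0.55
    #: gaps are truncated here; raise above 9 to exercise the gap exclusion
    uo_gap_max_hours: int = 8
    scr_interval_hours: float = 12.0
    los_hours_range: Tuple[float, float] = (36.0, 144.0)
    #: multiplicative lognormal noise scale on hourly urine flow
    noise_sd: float = 0.25
    #: fraction of controls given a transient (non-qualifying) oliguric dip
    control_oliguria_fraction: float = 0.35
    male_fraction: float = 0.63
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must be in [0, 1], got {self.prevalence}")
        if self.n_centers < 1:
            raise ValueError(f"n_centers must be >= 1, got {self.n_centers}")
        lo, hi = self.los_hours_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"los_hours_range must be positive and ordered, got {self.los_hours_range}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.uo_gap_geometric_p <= 1.0:
            raise ValueError(f"uo_gap_geometric_p must be in (0, 1], got {self.uo_gap_geometric_p}")
        if self.uo_gap_max_hours < 1:
            raise ValueError(f"uo_gap_max_hours must be >= 1, got {self.uo_gap_max_hours}")


@dataclass
class RawStay:
    patient_id: str
    center_id: str
    sex: str
    height_cm: float
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    died_in_hospital: bool
    uo_records: List[Tuple[pd.Timestamp, float]]
    scr_records: List[Tuple[pd.Timestamp, float]]
    dialysis: bool = False
    truth_label: str = "control"  # generator-only ground truth
    truth_stage: Optional[int] = None
    truth_onset_hour: Optional[int] = None
    # generator-internal hourly truths, kept for re-charting on injection
    _uo_hourly_mlkg: Optional[np.ndarray] = field(default=None, repr=False)
    _scr_hourly: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def los_hours(self) -> float:
        return (self.discharge_time - self.admit_time) / pd.Timedelta(hours=1)


def _chart_uo(uo_hourly_mlkg, ibw, admit, rng, cfg, boundaries_at=()):
    """Turn an hourly flow truth into cumulative charted volumes.

    Record times are integer hours; gap lengths are geometric truncated at
    ``uo_gap_max_hours``.  ``boundaries_at`` forces record boundaries (e.g.
    at oliguria onset/offset — charting tends to tighten when a patient
    deteriorates), which keeps injected episode edges crisp.
    """
    n = len(uo_hourly_mlkg)
    cuts = {0, n}
    t = 0
    while t < n:
        gap = min(int(rng.geometric(cfg.uo_gap_geometric_p)), cfg.uo_gap_max_hours)
        t += gap
        cuts.add(min(t, n))
    for b in boundaries_at:
        if 0 < b < n:
            cuts.add(int(b))
    cuts = sorted(cuts)
    uo_ml = uo_hourly_mlkg * ibw
    records = []
    for a, b in zip(cuts, cuts[1:]):
        vol = float(np.sum(uo_ml[a:b]))
        records.append((admit + pd.Timedelta(hours=b), vol))
    return records


def _chart_scr(scr_hourly, admit, rng, cfg, forced_hours=()):
    """Sample lab draws from the hourly creatinine truth."""
    n = len(scr_hourly)
    hours = {1}
    t = 1
    while t < n:
        t += max(1, int(round(cfg.scr_interval_hours * rng.uniform(0.7, 1.3))))
        if t < n:
            hours.add(t)
    for h in forced_hours:
        if 0 <= h < n:
            hours.add(int(h))
    return [(admit + pd.Timedelta(hours=h), float(scr_hourly[h])) for h in sorted(hours)]


def _control_hourly(n_hours, rng, cfg):
    """Hourly urine flow (ml/kg/h) and creatinine for a control stay."""
    base_flow = float(rng.lognormal(mean=np.log(1.1), sigma=0.35))
    noise = rng.lognormal(mean=0.0, sigma=cfg.noise_sd, size=n_hours) if cfg.noise_sd > 0 else np.ones(n_hours)
    uo = base_flow * noise
    if rng.random() < cfg.control_oliguria_fraction and n_hours > 16:
        # transient dip: below 0.5 ml/kg/h but too short for any AKIN clause
        dip_len = int(rng.integers(2, 7))
        s = int(rng.integers(1, n_hours - dip_len))
        uo[s : s + dip_len] = rng.uniform(0.35, 0.48, size=dip_len)
    base_scr = float(np.clip(rng.lognormal(np.log(0.85), 0.25), 0.55, 1.6))
    scr_noise = rng.uniform(0.97, 1.03, size=n_hours) if cfg.noise_sd > 0 else np.ones(n_hours)
    scr = base_scr * scr_noise
    return uo, scr


def _episode_plan(stage: int, rng) -> dict:
    """Pick the urine/creatinine shape of an injected episode."""
    if stage == 2:
        return {
            "uo_min_dur": 12,
            "depth_range": (0.3, 0.45),  # < 0.5 but never < 0.3 (stays stage 2)
            "scr_peak_mult": float(rng.uniform(2.2, 2.8)),
            "variant": "stage2",
        }
    if rng.random() < 0.5:
        variant = "anuria"
        plan = {"uo_min_dur": 12, "depth_range": (0.0, 0.0), "variant": variant}
    else:
        variant = "low_flow"
        plan = {"uo_min_dur": 24, "depth_range": (0.1, 0.25), "variant": variant}
    # half the stage-3 cases exercise the absolute >= 4.0 mg/dl clause, which
    # needs a high baseline so the ratio stays in 200-300% (anuria variant
    # only: its urine clause completes no later than stage 2's, so a same-hour
    # tie resolves to stage 3)
    if variant == "anuria" and rng.random() < 0.5:
        plan["scr_mode"] = "absolute"
    else:
        plan["scr_mode"] = "ratio"
        plan["scr_peak_mult"] = float(rng.uniform(3.3, 3.8))
    return plan


def inject_aki_episode(stay: RawStay, stage: int, onset_hour: int, rng) -> RawStay:
    """Return a copy of ``stay`` carrying an AKIN episode of the requested
    stage with the urine-output duration clause completing at ``onset_hour``.

    The stay must be long enough: the oliguric run starts at
    ``onset - min_duration`` and needs at least one pre-run hour, and a few
    post-onset hours must exist for the charted records to close.
    """
    if stage not in (2, 3):
        raise ValueError(f"stage must be 2 or 3, got {stage}")
    if stay._uo_hourly_mlkg is None:
        raise ValueError("inject_aki_episode requires a generator-produced stay")
    cfg = getattr(stay, "_cfg", None) or CohortConfig()
    n = len(stay._uo_hourly_mlkg)
    plan = _episode_plan(stage, rng)
    run_start = onset_hour - plan["uo_min_dur"]
    post = int(rng.integers(1, 5))
    run_end = min(n, onset_hour + 1 + post)
    if run_start < 1 or onset_hour + 2 > n:
        raise ValueError(
            f"stay of {n} h cannot host a stage-{stage} episode at onset {onset_hour} "
            f"(oliguria must start at hour {run_start} and data must extend past onset)"
        )

    uo = stay._uo_hourly_mlkg.copy()
    scr = stay._scr_hourly.copy()
    # Case phenotype: globally depressed diuresis with a pre-onset prodrome
    # of short non-qualifying oliguric dips (real severe-AKI stays show low
    # minimum and maximum diuresis throughout, not just peri-onset).  Dips
    # stay above 0.3 ml/kg/h and under 11 h, so no AKIN urine clause can
    # complete before the injected run; the flow between dips sits above
    # 0.5, so dips cannot merge into a qualifying run at noise-free settings.
    base_case = float(rng.uniform(0.55, 0.95))
    noise = (rng.lognormal(0.0, cfg.noise_sd, size=run_start)
             if cfg.noise_sd > 0 else np.ones(run_start))
    uo[:run_start] = base_case * noise
    t = int(rng.integers(6, 14))
    while t + 12 <= run_start - 2:
        dip_len = int(rng.integers(4, 11))
        dip_end = min(t + dip_len, run_start - 2)
        uo[t:dip_end] = rng.uniform(0.32, 0.48, size=dip_end - t)
        t = dip_end + int(rng.integers(4, 18))
    lo, hi = plan["depth_range"]
    uo[run_start:run_end] = 0.0 if hi == 0.0 else rng.uniform(lo, hi, size=run_end - run_start)
    if run_end < n:  # post-onset flow stays depressed
        tail = (rng.lognormal(0.0, cfg.noise_sd, size=n - run_end)
                if cfg.noise_sd > 0 else np.ones(n - run_end))
        uo[run_end:] = base_case * tail

    baseline = float(np.min(scr[: run_start]))
    if plan.get("scr_mode") == "absolute":
        # sCr >= 4.0 with acute rise >= 0.5; ratio kept inside 200-300%
        baseline = float(rng.uniform(1.45, 1.9))
        scr[:] = baseline
        peak = float(np.clip(rng.uniform(4.05, 4.4), 4.0, 2.95 * baseline))
    elif stage == 3:
        peak = plan["scr_peak_mult"] * baseline
    else:
        peak = plan["scr_peak_mult"] * baseline
    jump_hour = max(run_start + 1, onset_hour - int(rng.integers(2, 6)))
    if stage == 3:
        # jump over the 200-300% band between consecutive draws
        scr[jump_hour:] = peak
    else:
        ramp_len = max(1, onset_hour - jump_hour)
        ramp = np.linspace(baseline, peak, ramp_len + 1)[1:]
        scr[jump_hour : jump_hour + ramp_len] = ramp
        scr[jump_hour + ramp_len :] = peak

    admit = stay.admit_time
    uo_records = _chart_uo(uo, compute_ibw(stay.sex, stay.height_cm), admit, rng, cfg,
                           boundaries_at=(run_start, run_end))
    # force draws bracketing the jump so forward-fill shows the rise by onset
    scr_records = _chart_scr(scr, admit, rng, cfg,
                             forced_hours=(max(1, jump_hour - 1), min(n - 1, onset_hour - 1)))
    # drop any stray sampled draw landing inside the stage-3 jump ramp zone is
    # unnecessary: scr truth is a step function, every draw reads the truth
    return replace(
        stay,
        uo_records=uo_records,
        scr_records=scr_records,
        truth_label="case",
        truth_stage=stage,
        truth_onset_hour=int(onset_hour),
        died_in_hospital=bool(rng.random() < 0.3),
        _uo_hourly_mlkg=uo,
        _scr_hourly=scr,
    )


def _make_base_stay(i, cfg, rng, is_case: bool) -> RawStay:
    lo, hi = cfg.los_hours_range
    if is_case:
        # severe-AKI stays are long (real cohorts: cases stay ~2.5x longer);
        # the episode also needs room for lookback + lead + run
        lo = max(lo, 60.0)
        hi = max(hi, lo + 24.0)
    n_hours = int(rng.integers(int(lo), int(hi) + 1))
    sex = "male" if rng.random() < cfg.male_fraction else "female"
    height = float(rng.uniform(150.0, 195.0))
    admit = _BASE_TIME + pd.Timedelta(hours=int(rng.integers(0, 24 * 365)))
    uo, scr = _control_hourly(n_hours, rng, cfg)
    center = f"C{int(rng.integers(0, cfg.n_centers)):02d}"
    stay = RawStay(
        patient_id=f"P{i:05d}",
        center_id=center,
        sex=sex,
        height_cm=height,
        admit_time=admit,
        discharge_time=admit + pd.Timedelta(hours=n_hours),
        died_in_hospital=bool(rng.random() < 0.05),
        uo_records=[],
        scr_records=[],
        _uo_hourly_mlkg=uo,
        _scr_hourly=scr,
    )
    stay.uo_records = _chart_uo(uo, compute_ibw(sex, height), admit, rng, cfg)
    stay.scr_records = _chart_scr(scr, admit, rng, cfg)
    stay._cfg = cfg  # charting parameters travel with the stay for re-injection
    return stay


def generate_cohort(config: CohortConfig) -> List[RawStay]:
    """Generate a seeded synthetic cohort of :class:`RawStay`.

    Deterministic given ``config.seed``; the expected case fraction equals
    ``config.prevalence`` (Bernoulli per patient).  Injected onsets are at
    hour >= 26, well past the 19-h minimum a 12-h lookback + 6-h lead needs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stays = []
    for i in range(config.n_patients):
        is_case = bool(rng.random() < config.prevalence)
        stay = _make_base_stay(i, config, rng, is_case)
        if is_case:
            n = int(stay.los_hours)
            stage = 2 if rng.random() < 0.6 else 3
            onset = int(rng.integers(26, n - 4))
            stay = inject_aki_episode(stay, stage, onset, rng)
        stays.append(stay)
    return stays


def write_cohort_csvs(stays, out_dir) -> None:
    """Write the long-format contract tables: patients.csv, urine_output.csv,
    creatinine.csv (ISO-8601 timestamps) and the generator-only truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients, uo_rows, scr_rows, truth = [], [], [], []
    for s in stays:
        patients.append(
            {
                "patient_id": s.patient_id,
                "center_id": s.center_id,
                "sex": s.sex,
                "height_cm": round(s.height_cm, 1),
                "admit_time": s.admit_time.isoformat(),
                "discharge_time": s.discharge_time.isoformat(),
                "died_in_hospital": s.died_in_hospital,
                "dialysis": s.dialysis,
            }
        )
        for t, v in s.uo_records:
            uo_rows.append({"patient_id": s.patient_id, "timestamp": t.isoformat(), "volume_ml": round(v, 3)})
        for t, v in s.scr_records:
            scr_rows.append({"patient_id": s.patient_id, "timestamp": t.isoformat(), "scr_mg_dl": round(v, 3)})
        truth.append(
            {
                "patient_id": s.patient_id,
                "label": s.truth_label,
                "stage": s.truth_stage if s.truth_stage is not None else "",
                "onset_hour": s.truth_onset_hour if s.truth_onset_hour is not None else "",
            }
        )
    pd.DataFrame(patients).to_csv(out / "patients.csv", index=False)
    pd.DataFrame(uo_rows).to_csv(out / "urine_output.csv", index=False)
    pd.DataFrame(scr_rows).to_csv(out / "creatinine.csv", index=False)
    pd.DataFrame(truth).to_csv(out / "truth.csv", index=False)


def read_cohort_csvs(in_dir) -> List[RawStay]:
    """Read the three contract tables back into :class:`RawStay` objects
    (no ground truth: the pipeline proper never sees truth.csv)."""
    ind = Path(in_dir)
    pats = pd.read_csv(ind / "patients.csv", parse_dates=["admit_time", "discharge_time"])
    uo = pd.read_csv(ind / "urine_output.csv", parse_dates=["timestamp"])
    scr = pd.read_csv(ind / "creatinine.csv", parse_dates=["timestamp"])
    uo_by = {k: list(zip(g["timestamp"], g["volume_ml"])) for k, g in uo.groupby("patient_id")}
    scr_by = {k: list(zip(g["timestamp"], g["scr_mg_dl"])) for k, g in scr.groupby("patient_id")}
    stays = []
    for _, r in pats.iterrows():
        stays.append(
            RawStay(
                patient_id=r.patient_id,
                center_id=r.center_id,
                sex=r.sex,
                height_cm=float(r.height_cm),
                admit_time=r.admit_time,
                discharge_time=r.discharge_time,
                died_in_hospital=bool(r.died_in_hospital),
                dialysis=bool(r.dialysis),
                uo_records=sorted(uo_by.get(r.patient_id, [])),
                scr_records=sorted(scr_by.get(r.patient_id, [])),
            )
        )
    return stays
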