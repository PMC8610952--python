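"""End-to-end driver: simulate -> preprocess -> label -> split -> fit -> evaluate.

Each stage logs a structured line with counts (the exclusion waterfall
mirrors the cohort-accounting style of multi-center ICU studies: every
patient is counted once under the first exclusion reason that applies),
and, when an output directory is given, writes its artifact as CSV/JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import cnn, evaluate, features, labeling, preprocess, synthetic

log = logging.getLogger("akiwatch")


@dataclass
class PipelineConfig:
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    input_dir: Optional[str] = None  # read CSVs instead of simulating
    split_seed: int = 17
    sample_seed: int = 23
    model: cnn.ModelConfig = field(default_factory=cnn.ModelConfig)
    models: tuple = ("logistic_multi", "logistic_single", "cnn")
    coupling_hours: int = labeling.DEFAULT_COUPLING_H
    community_acquired_horizon_h: int = preprocess.COMMUNITY_ACQUIRED_HORIZON_H
    target_sensitivity: float = evaluate.DEFAULT_TARGET_SENSITIVITY
    lead_hours: int = evaluate.DEFAULT_LEAD_H
    n_resamples: int = 100
    single_feature_rule: features.SingleFeatureRule = field(default_factory=features.SingleFeatureRule)
    #: training windows kept per patient (subsampled for speed; prediction
    #: always uses every window)
    max_train_windows_per_patient: int = 25

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat ``key = value`` config file; dotted keys reach sub-configs
        (e.g. ``cohort.n_patients = 500``)."""
        cfg = cls()
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            target, attr = cfg, key
            while "." in attr:
                head, attr = attr.split(".", 1)
                target = getattr(target, head)
            if not hasattr(target, attr):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(target, attr)
            if isinstance(current, bool):
                parsed = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                parsed = int(value)
            elif isinstance(current, float):
                parsed = float(value)
            elif isinstance(current, tuple):
                parsed = tuple(type(current[0])(v) for v in value.split(","))
            else:
                parsed = value
            setattr(target, attr, parsed)
        return cfg


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _exclusion_waterfall(reports):
    waterfall = {r: 0 for r in preprocess.EXCLUSION_REASONS}
    for rep in reports:
        if rep.excluded:
            waterfall[rep.reasons[0]] += 1
    return waterfall


def run_pipeline(config: PipelineConfig, out_dir=None, return_artifacts: bool = False):
    """Run the full analysis; returns the evaluation report as a dict
    (with ``return_artifacts=True``: ``(report, artifacts)`` where the
    artifacts carry the fitted objects and prepared arrays for reuse)."""
    artifacts = {}
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- 1. cohort -----------------------------------------------------
    if config.input_dir:
        stays = synthetic.read_cohort_csvs(config.input_dir)
    else:
        stays = synthetic.generate_cohort(config.cohort)
    log.info("cohort: %d stays (seed=%s)", len(stays), getattr(config.cohort, "seed", "file"))
    if out and not config.input_dir:
        synthetic.write_cohort_csvs(stays, out / "cohort")

    # ---- 2. preprocess -------------------------------------------------
    series_by, flags_list = {}, []
    for stay in stays:
        try:
            series, flags = preprocess.preprocess_stay(stay)
        except ValueError as exc:
            raise PipelineError("preprocess", f"patient {stay.patient_id}: {exc}") from exc
        series_by[stay.patient_id] = series
        flags_list.append(flags)

    # ---- 3. label (needed before exclusions for community-acquired AKI) -
    episodes: Dict[str, labeling.AkiEpisode] = {}
    for flags in flags_list:
        s = series_by[flags.patient_id]
        if np.isnan(flags.baseline_scr):
            continue
        ep = labeling.stage_episode(s, flags.baseline_scr, config.coupling_hours)
        if ep is not None:
            episodes[flags.patient_id] = ep
            if ep.onset_hour <= config.community_acquired_horizon_h:
                flags.community_acquired = True

    # ---- 4. exclusions ---------------------------------------------------
    kept_ids, reports = preprocess.apply_exclusions(flags_list)
    waterfall = _exclusion_waterfall(reports)
    log.info("exclusions: %d in, %d kept, waterfall=%s", len(stays), len(kept_ids), waterfall)
    assert len(stays) == len(kept_ids) + sum(waterfall.values())

    # cases whose onset is too early for any prediction are dropped (logged)
    too_early = [pid for pid in kept_ids
                 if pid in episodes and episodes[pid].onset_hour < labeling.MIN_PREDICTABLE_ONSET_H]
    if too_early:
        log.info("dropping %d cases with onset < %d h: %s", len(too_early),
                 labeling.MIN_PREDICTABLE_ONSET_H, too_early[:10])
        kept_ids = [pid for pid in kept_ids if pid not in set(too_early)]

    labels = {pid: ("case" if pid in episodes else "control") for pid in kept_ids}
    n_cases = sum(1 for v in labels.values() if v == "case")
    if out:
        pd.DataFrame(
            [{"patient_id": r.patient_id, "excluded": r.excluded, "reasons": ";".join(r.reasons)}
             for r in reports]
        ).to_csv(out / "exclusions.csv", index=False)
        pd.DataFrame(
            [{"patient_id": e.patient_id, "stage": e.stage, "onset_hour": e.onset_hour,
              "scr_criterion": e.scr_criterion, "uo_criterion": e.uo_criterion}
             for e in episodes.values()]
        ).to_csv(out / "episodes.csv", index=False)

    # ---- 5. splits -------------------------------------------------------
    assignment = evaluate.assign_splits(kept_ids, config.split_seed)
    split_of = {name: [pid for pid in kept_ids if assignment[pid] == name]
                for name in evaluate.SPLIT_NAMES}
    overlap = set()
    seen = set()
    for name in evaluate.SPLIT_NAMES:
        overlap |= seen & set(split_of[name])
        seen |= set(split_of[name])
    assert not overlap, f"patients in multiple splits: {sorted(overlap)[:5]}"
    log.info("splits: %s", {k: len(v) for k, v in split_of.items()})

    # ---- 6. truncate case series ----------------------------------------
    working: Dict[str, preprocess.HourlySeries] = {}
    for pid in kept_ids:
        s = series_by[pid]
        if labels[pid] == "case":
            s = labeling.truncate_case_series(s, episodes[pid].onset_hour)
        working[pid] = s

    report = {
        "n_stays_in": len(stays),
        "n_kept": len(kept_ids),
        "n_cases": n_cases,
        "case_fraction": n_cases / len(kept_ids) if kept_ids else 0.0,
        "exclusion_waterfall": waterfall,
        "n_cases_dropped_early_onset": len(too_early),
        "splits": {k: len(v) for k, v in split_of.items()},
    }

    def split_series(name):
        return [working[pid] for pid in split_of[name]]

    def check_two_classes(name, stage):
        labs = {labels[pid] for pid in split_of[name]}
        if len(labs) < 2:
            raise PipelineError(stage, f"single-class {name} split (labels={labs})")

    # ---- 7. logistic models ---------------------------------------------
    if "logistic_multi" in config.models or "logistic_single" in config.models:
        check_two_classes("train", "featurize")
        check_two_classes("test", "featurize")
        tables = {name: features.feature_table(split_series(name), labels)
                  for name in ("train", "test")}
        sampled = {name: features.sample_one_per_patient(tables[name], config.sample_seed + i)
                   for i, name in enumerate(("train", "test"))}
        if out:
            tables["train"].to_csv(out / "features_train.csv", index=False)

        if "logistic_multi" in config.models:
            model = features.fit_multifeature_logistic(sampled["train"])
            p_test = model.predict_proba(sampled["test"])
            y_test = (sampled["test"]["label"] == "case").to_numpy(dtype=int)
            perf = evaluate.resampled_performance(
                p_test, y_test, config.n_resamples, seed=config.split_seed,
                target_sensitivity=config.target_sensitivity)
            roc = evaluate.roc_curve_and_auc(p_test, y_test)
            report["logistic_multi"] = {
                "auc": roc.auc, **perf,
                "knee": asdict(evaluate.knee_point(roc)),
                "sens80": asdict(evaluate.operating_point_at_sensitivity(roc, config.target_sensitivity)),
                "coefficients": model.coefficients,
            }
            if out:
                (out / "logistic_coefficients.json").write_text(json.dumps(model.coefficients, indent=1))
            log.info("logistic_multi: test AUC %.3f", roc.auc)

        if "logistic_single" in config.models:
            rule = config.single_feature_rule
            f_col = sampled["test"][f"f{rule.window_w}"].to_numpy(dtype=float)
            y_test = (sampled["test"]["label"] == "case").to_numpy(dtype=int)
            roc = evaluate.roc_curve_and_auc(-f_col, y_test)  # low flow = high risk
            alarms = f_col < rule.threshold_mlkg_h
            sens = float(np.mean(alarms[y_test == 1])) if (y_test == 1).any() else np.nan
            spec = float(np.mean(~alarms[y_test == 0]))
            lp, ln = evaluate.likelihood_ratios(sens, spec)
            report["logistic_single"] = {
                "window_w": rule.window_w, "threshold": rule.threshold_mlkg_h,
                "auc": roc.auc, "sensitivity": sens, "specificity": spec,
                "lr_pos": lp, "lr_neg": ln,
            }
            log.info("logistic_single(w=%d): test AUC %.3f", rule.window_w, roc.auc)

    # ---- 8. CNN ----------------------------------------------------------
    if "cnn" in config.models:
        for name in ("train", "validation", "calibration", "test"):
            check_two_classes(name, "train")
        samples = {name: cnn.make_window_samples(split_series(name), labels)
                   for name in evaluate.SPLIT_NAMES}
        tr = _subsample_windows(samples["train"], config.max_train_windows_per_patient,
                                config.model.seed)
        model = cnn.CnnRiskModel(config.model)
        history = cnn.train_model(model, tr.X, tr.y, samples["validation"].X,
                                  samples["validation"].y, config.model)
        calibrator = cnn.calibrate(model, samples["calibration"].X, samples["calibration"].y)
        log.info("cnn: %d params, %d epochs, best val AUC %.3f",
                 model.n_parameters, len(history["val_auc"]), max(history["val_auc"]))

        # patient-level scores: max hourly score pre-onset (cases) / anywhere
        test_scores, test_labels, test_stages, score_frames = [], [], [], {}
        for pid in split_of["test"]:
            frame = cnn.predict_risk(model, calibrator, working[pid])
            score_frames[pid] = frame
            test_scores.append(float(frame["score"].max()))
            test_labels.append(1 if labels[pid] == "case" else 0)
            test_stages.append(episodes[pid].stage if pid in episodes else None)
        test_scores = np.asarray(test_scores)
        test_labels = np.asarray(test_labels)

        roc = evaluate.roc_curve_and_auc(test_scores, test_labels)
        knee = evaluate.knee_point(roc)
        s80 = evaluate.operating_point_at_sensitivity(roc, config.target_sensitivity)
        perf = evaluate.resampled_performance(
            test_scores, test_labels, config.n_resamples, seed=config.split_seed,
            target_sensitivity=config.target_sensitivity)

        case_ids = [pid for pid in split_of["test"] if labels[pid] == "case"]
        first_alarms = [evaluate.first_alarm_hour(score_frames[pid], knee.threshold)
                        for pid in case_ids]
        onsets = [episodes[pid].onset_hour for pid in case_ids]
        early = (evaluate.early_detection_fraction(first_alarms, onsets, config.lead_hours)
                 if case_ids else np.nan)

        win = samples["test"]
        window_auc = evaluate.roc_curve_and_auc(
            _score_windows(model, calibrator, win.X), win.y).auc if len(np.unique(win.y)) > 1 else np.nan

        report["cnn"] = {
            "auc": roc.auc, **perf,
            "knee": asdict(knee), "sens80": asdict(s80),
            "early_detection_fraction": early,
            "per_stage": evaluate.per_stage_breakdown(test_scores, test_labels, test_stages, knee.threshold),
            "window_level_auc": window_auc,
            "n_parameters": model.n_parameters,
            "epochs_run": len(history["val_auc"]),
        }
        artifacts.update(model=model, calibrator=calibrator, samples=samples,
                         test_scores=test_scores, test_labels=test_labels,
                         score_frames=score_frames)
        if out:
            cnn.save_model(model, out / "cnn_model.json")
            pd.concat(score_frames.values()).to_csv(out / "risk_scores.csv", index=False)
        log.info("cnn: test AUC %.3f, knee sens %.2f spec %.2f, early-detection %.2f",
                 roc.auc, knee.sensitivity, knee.specificity, early)

    if out:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=_jsonable))
    if return_artifacts:
        artifacts.update(labels=labels, episodes=episodes, working=working,
                         split_of=split_of, assignment=assignment)
        return report, artifacts
    return report


def _subsample_windows(samples: cnn.WindowSamples, max_per_patient: int, seed: int) -> cnn.WindowSamples:
    rng = np.random.default_rng(seed + 101)
    keep = []
    for pid in pd.unique(samples.patient_ids):
        idx = np.flatnonzero(samples.patient_ids == pid)
        if len(idx) > max_per_patient:
            idx = rng.choice(idx, size=max_per_patient, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return cnn.WindowSamples(samples.X[keep], samples.y[keep],
                             samples.patient_ids[keep], samples.window_end_hours[keep])


def _score_windows(model, calibrator, X):
    p = cnn._predict_in_batches(model, np.asarray(X, dtype=float))
    return calibrator.transform(p) if calibrator is not None else p


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
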