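"""ROC analysis, operating points, likelihood ratios, splits, early detection."""

import itertools

import numpy as np
import pytest

from akiwatch.evaluate import (
    assign_splits,
    early_detection_fraction,
    knee_point,
    likelihood_ratios,
    operating_point_at_sensitivity,
    per_stage_breakdown,
    resampled_performance,
    roc_curve_and_auc,
)


def pair_counting_auc(scores, labels):
    """Oracle: fraction of case-control pairs ranked correctly (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for n in controls:
            total += 1.0 if c > n else (0.5 if c == n else 0.0)
    return total / (len(cases) * len(controls))


class TestSplits:
    def test_proportions_on_100_patients(self):
        ids = [f"p{i}" for i in range(100)]
        assignment = assign_splits(ids, seed=0)
        counts = {k: sum(1 for v in assignment.values() if v == k) for k in set(assignment.values())}
        assert counts == {"train": 60, "validation": 10, "test": 20, "calibration": 10}

    def test_partition_property_and_determinism(self):
        ids = [f"p{i}" for i in range(137)]
        a = assign_splits(ids, seed=5)
        b = assign_splits(ids, seed=5)
        assert a == b
        assert set(a) == set(ids)  # every patient assigned exactly once
        n = len(ids)
        for name, p in zip(("train", "validation", "test", "calibration"), (0.6, 0.1, 0.2, 0.1)):
            count = sum(1 for v in a.values() if v == name)
            assert abs(count - p * n) <= 1

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            assign_splits([f"p{i}" for i in range(9)], seed=0)


class TestRocAuc:
    def test_perfect_ranking(self):
        roc = roc_curve_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_complete_ties_give_half(self):
        roc = roc_curve_and_auc([0.5] * 10, [1, 0] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_toy_set_matches_pair_counting(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        roc = roc_curve_and_auc(scores, labels)
        assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_random_sets_match_pair_counting(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            roc = roc_curve_and_auc(scores, labels)
            assert roc.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_curve_and_auc([0.1, 0.2], [1, 1])


class TestLikelihoodRatios:
    @pytest.mark.parametrize(
        "sens, spec, lr_pos, lr_neg",
        [
            (0.774, 0.780, 3.52, 0.29),  # knee-style operating point
            (0.80, 0.84, 5.00, 0.24),
            (0.5, 0.5, 1.0, 1.0),  # uninformative test
        ],
    )
    def test_known_pairs(self, sens, spec, lr_pos, lr_neg):
        lp, ln = likelihood_ratios(sens, spec)
        assert lp == pytest.approx(lr_pos, abs=0.005)
        assert ln == pytest.approx(lr_neg, abs=0.005)

    def test_perfect_specificity_gives_infinite_lr_pos(self):
        lp, ln = likelihood_ratios(0.9, 1.0)
        assert np.isinf(lp) and ln == pytest.approx(0.1)


def _toy_roc():
    scores = [0.05, 0.15, 0.30, 0.45, 0.55, 0.70, 0.80, 0.95]
    labels = [0, 0, 1, 0, 1, 0, 1, 1]
    return roc_curve_and_auc(scores, labels), scores, labels


class TestOperatingPoints:
    def test_sensitivity_target_matches_exhaustive_scan(self):
        roc, scores, labels = _toy_roc()
        op = operating_point_at_sensitivity(roc, 0.80)
        # oracle: scan all candidate thresholds, keep max specificity with sens >= 0.8
        best = None
        for thr in sorted(set(scores), reverse=True):
            sens = np.mean([s >= thr for s, l in zip(scores, labels) if l == 1])
            spec = np.mean([s < thr for s, l in zip(scores, labels) if l == 0])
            if sens >= 0.80 and (best is None or spec > best[1]):
                best = (sens, spec)
        assert (op.sensitivity, op.specificity) == pytest.approx(best)

    def test_boundary_targets(self):
        roc, _, _ = _toy_roc()
        top = operating_point_at_sensitivity(roc, 0.0)
        assert top.sensitivity >= 0.0 and top.specificity == 1.0
        bottom = operating_point_at_sensitivity(roc, 1.0)
        assert bottom.sensitivity == 1.0

    def test_lr_consistency_at_reported_points(self):
        roc, _, _ = _toy_roc()
        for op in (operating_point_at_sensitivity(roc, 0.8), knee_point(roc)):
            lp, ln = likelihood_ratios(op.sensitivity, op.specificity)
            assert op.lr_pos == pytest.approx(lp) and op.lr_neg == pytest.approx(ln)


class TestKneePoint:
    def test_perfect_vertex_is_chosen(self):
        roc = roc_curve_and_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        op = knee_point(roc)
        assert (op.sensitivity, op.specificity) == (1.0, 1.0)

    def test_matches_exhaustive_vertex_scan(self):
        roc, _, _ = _toy_roc()
        op = knee_point(roc)
        dists = np.sqrt(roc.fpr**2 + (1 - roc.tpr) ** 2)
        assert np.sqrt((1 - op.specificity) ** 2 + (1 - op.sensitivity) ** 2) == pytest.approx(dists.min())

    def test_tie_breaks_toward_sensitivity(self):
        # symmetric ROC: (fpr, tpr) = (0, 0.6) and (0.4, 1.0) are equidistant
        scores = [0.9, 0.9, 0.9, 0.5, 0.5, 0.1, 0.1, 0.1, 0.5, 0.5]
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        roc = roc_curve_and_auc(scores, labels)
        op = knee_point(roc)
        assert op.sensitivity == 1.0

    def test_youden_local_optimality(self):
        rng = np.random.default_rng(9)
        scores = rng.random(60)
        labels = (rng.random(60) < 0.4).astype(int)
        roc = roc_curve_and_auc(scores, labels)
        op = knee_point(roc)
        j = roc.tpr - roc.fpr
        idx = int(np.argmin(np.abs(roc.thresholds - op.threshold)))
        neighbors = [j[i] for i in (idx - 1, idx + 1) if 0 <= i < len(j)]
        assert not all(j[idx] < nb for nb in neighbors)

    def test_youden_variant_maximizes_j(self):
        roc, _, _ = _toy_roc()
        op = knee_point(roc, method="youden")
        assert op.sensitivity - (1 - op.specificity) == pytest.approx(np.max(roc.tpr - roc.fpr))


class TestEarlyDetection:
    def test_hand_counted_leads(self):
        onsets = [30, 30, 30, 40, 40]
        leads = [14, 13, 11, 20, 6]
        alarms = [o - l for o, l in zip(onsets, leads)]
        assert early_detection_fraction(alarms, onsets, lead=12) == pytest.approx(3 / 5)

    def test_all_early_and_none(self):
        assert early_detection_fraction([0, 0], [30, 40], lead=12) == 1.0
        assert early_detection_fraction([None, None], [30, 40], lead=12) == 0.0

    def test_monotone_in_required_lead(self):
        rng = np.random.default_rng(2)
        onsets = rng.integers(24, 100, size=40)
        alarms = [int(o - rng.integers(0, 30)) if rng.random() < 0.8 else None for o in onsets]
        fracs = [early_detection_fraction(alarms, onsets, lead) for lead in range(0, 30, 3)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))


class TestResampling:
    def test_full_pool_single_resample_has_zero_sd(self):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        labels = (rng.random(100) < 0.3).astype(int)
        out = resampled_performance(scores, labels, n_resamples=1, frac=1.0, seed=0)
        assert out["auc_sd"] == 0.0

    def test_same_seed_identical_summary(self):
        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.2).astype(int)
        a = resampled_performance(scores, labels, n_resamples=20, seed=3)
        b = resampled_performance(scores, labels, n_resamples=20, seed=3)
        assert a == b

    def test_sd_shrinks_with_resample_size(self):
        rng = np.random.default_rng(6)
        scores = rng.random(600)
        labels = (rng.random(600) < 0.25).astype(int)
        sds = [resampled_performance(scores, labels, n_resamples=60, frac=f, seed=1)["auc_sd"]
               for f in (0.2, 0.5, 0.9)]
        assert sds[0] > sds[1] > sds[2]


class TestPerStage:
    def test_table_style_lr_values(self):
        lp2, ln2 = likelihood_ratios(0.80, 0.836)
        lp3, ln3 = likelihood_ratios(0.83, 0.836)
        assert ln2 == pytest.approx(0.24, abs=0.005)
        assert lp3 == pytest.approx(5.06, abs=0.005)

    def test_identical_scores_give_identical_stage_metrics(self):
        scores = np.array([90, 90, 10, 10, 10, 10, 90, 90])
        labels = np.array([1, 1, 0, 0, 0, 0, 1, 1])
        stages = [2, 2, None, None, None, None, 3, 3]
        out = per_stage_breakdown(scores, labels, stages, threshold=50)
        assert out[2]["sensitivity"] == out[3]["sensitivity"]
        assert out[2]["specificity"] == out[3]["specificity"]
        assert out[2]["lr_pos"] == out[3]["lr_pos"]

    def test_missing_stage_is_omitted(self):
        scores = np.array([90, 10, 10])
        labels = np.array([1, 0, 0])
        out = per_stage_breakdown(scores, labels, [2, None, None], threshold=50)
        assert 3 not in out and out[2]["n_cases"] == 1
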