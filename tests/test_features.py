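"""Minimum-moving-average features and the logistic risk models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from akiwatch import features, labeling, preprocess, synthetic
from akiwatch.features import (
    FEATURE_COLUMNS,
    SingleFeatureRule,
    apply_single_feature_rule,
    extract_features,
    feature_table,
    fit_multifeature_logistic,
    min_moving_average,
    sample_one_per_patient,
)

from conftest import make_series


def brute_force_mma(uo, w):
    return min(np.mean(uo[s : s + w]) for s in range(len(uo) - w + 1))


class TestMinMovingAverage:
    @pytest.mark.parametrize(
        "uo, w, expected",
        [
            ([0.5] * 20, 5, 0.5),
            ([0.8, 0.6, 0.4, 0.2, 0.4, 0.6], 3, (0.4 + 0.2 + 0.4) / 3),
            ([1, 1, 0, 0, 1, 1], 2, 0.0),
        ],
    )
    def test_hand_examples(self, uo, w, expected):
        assert min_moving_average(uo, w) == pytest.approx(expected)

    def test_series_shorter_than_window_raises(self):
        with pytest.raises(ValueError):
            min_moving_average([1.0, 2.0], 3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 5.0), min_size=12, max_size=200))
    def test_matches_brute_force_for_all_windows(self, uo):
        for w in features.WINDOW_RANGE:
            assert min_moving_average(uo, w) == pytest.approx(brute_force_mma(np.asarray(uo), w), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 5.0), min_size=12, max_size=60),
           st.floats(0.1, 10.0))
    def test_scaling_equivariance(self, uo, k):
        fv = extract_features(uo, 12)
        fv_scaled = extract_features(np.asarray(uo) * k, 12)
        for w in features.WINDOW_RANGE:
            assert fv_scaled.features[w] == pytest.approx(k * fv.features[w], rel=1e-9)


class TestExtractFeatures:
    def test_constant_series_gives_constant_features(self):
        fv = extract_features(np.full(12, 0.7), 12)
        assert all(v == pytest.approx(0.7) for v in fv.features.values())
        assert len(fv.features) == 11

    def test_appending_low_hour_never_increases_features(self):
        rng = np.random.default_rng(1)
        uo = rng.uniform(0.5, 2.0, size=30)
        before = extract_features(uo, 30).features
        after = extract_features(np.append(uo, 0.01), 31).features
        for w in features.WINDOW_RANGE:
            assert after[w] <= before[w] + 1e-12

    def test_too_early_hour_raises(self):
        with pytest.raises(ValueError):
            extract_features(np.ones(11), 11)

    def test_feature_table_matches_direct_extraction(self):
        """The running-minimum fast path equals per-hour recomputation."""
        rng = np.random.default_rng(2)
        s = make_series(rng.uniform(0.0, 3.0, size=40), patient_id="A")
        table = feature_table([s], {"A": "case"})
        assert list(table["hour"]) == list(range(12, 41))
        for _, row in table.iterrows():
            fv = extract_features(s.uo_mlkg_h, int(row["hour"]))
            for w in features.WINDOW_RANGE:
                assert row[f"f{w}"] == pytest.approx(fv.features[w], abs=1e-12)


class TestSampling:
    def _table(self, n_rows, pid="A"):
        rows = [{"patient_id": pid, "hour": 12 + i, "label": "control",
                 **{c: float(i) for c in FEATURE_COLUMNS}} for i in range(n_rows)]
        return pd.DataFrame(rows)

    def test_single_row_patient_returns_it(self):
        out = sample_one_per_patient(self._table(1), seed=0)
        assert len(out) == 1 and out.iloc[0]["hour"] == 12

    def test_same_seed_same_selection(self):
        table = pd.concat([self._table(5, "A"), self._table(8, "B")])
        a = sample_one_per_patient(table, seed=11)
        b = sample_one_per_patient(table, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_selection_is_uniform(self):
        table = self._table(4)
        counts = np.zeros(4)
        for seed in range(10000):
            counts[int(sample_one_per_patient(table, seed).iloc[0]["hour"]) - 12] += 1
        assert np.all(np.abs(counts / 10000 - 0.25) < 0.02)


class TestMultiFeatureLogistic:
    def _toy(self, n=40, separable=True, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            case = i < n // 2
            level = 0.0 if (case and separable) else rng.uniform(0.8, 1.2)
            rows.append({"patient_id": f"p{i}", "hour": 12,
                         "label": "case" if case else "control",
                         **{c: level for c in FEATURE_COLUMNS}})
        return pd.DataFrame(rows)

    def test_separable_training_data_reaches_auc_one(self):
        table = self._toy()
        model = fit_multifeature_logistic(table, regularization=1.0)
        p = model.predict_proba(table)
        y = (table["label"] == "case").astype(int)
        assert roc_auc_score(y, p) == 1.0

    def test_single_class_raises(self):
        table = self._toy()
        with pytest.raises(ValueError):
            fit_multifeature_logistic(table[table["label"] == "case"])

    def test_permuted_labels_score_at_chance(self):
        """After shuffling all labels, held-out AUC sits near 0.5 (shuffled
        labels are independent of the features; mean of 3 permutations
        keeps Monte-Carlo error small)."""
        rng = np.random.default_rng(4)
        n = 2000
        X = rng.uniform(0.2, 1.5, size=(n, 11))
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        table["patient_id"] = [f"p{i}" for i in range(n)]
        table["hour"] = 12
        table["label"] = np.where(X[:, 0] < 0.5, "case", "control")
        aucs = []
        for perm_seed in range(3):
            prng = np.random.default_rng(perm_seed)
            shuffled = table.copy()
            shuffled["label"] = prng.permutation(shuffled["label"].to_numpy())
            train, test = shuffled.iloc[: n // 2], shuffled.iloc[n // 2 :]
            model = fit_multifeature_logistic(train, regularization=1.0)
            y = (test["label"] == "case").astype(int)
            aucs.append(roc_auc_score(y, model.predict_proba(test)))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_coefficient_recovery_against_mle_oracle(self):
        """On data simulated from a known logistic model the fit recovers the
        generating coefficients within 2 SE (SEs from the statsmodels MLE)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n = 5000
        X = rng.normal(size=(n, 11)) * 0.8
        beta = np.linspace(-1.0, 1.0, 11)
        logits = X @ beta - 0.3
        y = rng.random(n) < 1 / (1 + np.exp(-logits))
        table = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        table["patient_id"] = [f"p{i}" for i in range(n)]
        table["hour"] = 12
        table["label"] = np.where(y, "case", "control")
        model = fit_multifeature_logistic(table)
        sm_fit = sm.Logit(y.astype(int), sm.add_constant(X)).fit(disp=0)
        se = sm_fit.bse
        est = np.array([model.coefficients[c] for c in FEATURE_COLUMNS])
        z = np.abs(np.append(model.coefficients["intercept"] - (-0.3), est - beta)) / se
        # 12 simultaneous checks: most within 2 SE, none grossly off
        assert np.mean(z <= 2.0) >= 0.75
        assert np.all(z <= 3.5)
        # and the two MLE routes agree with each other
        np.testing.assert_allclose(est, sm_fit.params[1:], atol=0.02)


class TestSingleFeatureRule:
    @pytest.mark.parametrize("f7, alarm", [(0.30, True), (0.372, False), (1.0, False)])
    def test_strict_threshold(self, f7, alarm):
        rule = SingleFeatureRule(window_w=7, threshold_mlkg_h=0.372)
        fv = features.FeatureVector("p", 12, {w: f7 for w in features.WINDOW_RANGE}, "control")
        assert apply_single_feature_rule(fv, rule) is alarm

    def test_published_threshold_table(self):
        assert features.PUBLISHED_THRESHOLDS[7] == 0.372
        assert SingleFeatureRule().threshold_mlkg_h == 0.372

    def test_invalid_rule_raises(self):
        with pytest.raises(ValueError):
            SingleFeatureRule(window_w=13)
        with pytest.raises(ValueError):
            SingleFeatureRule(threshold_mlkg_h=0.0)


class TestEndToEndSignal:
    def test_heldout_auc_exceeds_08_on_injected_cohort(self):
        """Multi-feature logistic separates injected oliguric cases from
        controls on a held-out patient split."""
        cfg = synthetic.CohortConfig(n_patients=800, prevalence=0.05, seed=21)
        stays = synthetic.generate_cohort(cfg)
        labels, series_list = {}, []
        for stay in stays:
            series, flags = preprocess.preprocess_stay(stay)
            ep = labeling.stage_episode(series, flags.baseline_scr)
            if ep is not None:
                series = labeling.truncate_case_series(series, ep.onset_hour)
                labels[stay.patient_id] = "case"
            else:
                labels[stay.patient_id] = "control"
            series_list.append(series)
        split = int(0.6 * len(series_list))
        train_tab = feature_table(series_list[:split], labels)
        test_tab = feature_table(series_list[split:], labels)
        train = sample_one_per_patient(train_tab, seed=1)
        test = sample_one_per_patient(test_tab, seed=2)
        model = fit_multifeature_logistic(train)
        y = (test["label"] == "case").astype(int)
        assert roc_auc_score(y, model.predict_proba(test)) > 0.8
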