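"""Metrics against brute-force oracles, calibration, dose-response, embeddings."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from oblfp import evalrep, models
from oblfp.evalrep import (CalibrationSummary, ConfusionCounts,
                           aggregate_folds, auc, calibration_summary,
                           concentration_table, confusion, latency_benchmark,
                           metrics, tsne_embedding)


def brute_force_metrics(labels, preds):
    """Independent oracle: enumerate every (label, prediction) pair."""
    tp = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 1)
    tn = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 0)
    fp = sum(1 for l, p in zip(labels, preds) if l == 0 and p == 1)
    fn = sum(1 for l, p in zip(labels, preds) if l == 1 and p == 0)
    out = {}
    out["accuracy"] = (tp + tn) / len(labels) if labels else None
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["recall"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (tn + fp) if tn + fp else None
    if out["precision"] is None or out["recall"] is None or \
            out["precision"] + out["recall"] == 0:
        out["f1"] = None
    else:
        out["f1"] = (2 * out["precision"] * out["recall"]
                     / (out["precision"] + out["recall"]))
    return (tp, tn, fp, fn), out


def brute_force_auc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return None
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_enumerated_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_predictions(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == 0 and c.fn == 0

    def test_all_positive_predictions(self):
        c = confusion([1, 1, 1, 0, 0], [1, 1, 1, 1, 1])
        assert c.tp == 3 and c.fp == 2 and c.tn == 0 and c.fn == 0

    def test_total_matches_trial_count(self):
        rng = np.random.default_rng(0)
        labels, preds = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        assert confusion(labels, preds).total == 50

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])


class TestMetrics:
    def test_hand_computed_example(self):
        rep = metrics(ConfusionCounts(tp=8, tn=9, fp=1, fn=2))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(8 / 9)
        assert rep.recall == pytest.approx(0.8)
        assert rep.specificity == pytest.approx(0.9)
        assert rep.f1 == pytest.approx(2 * (8 / 9) * 0.8 / ((8 / 9) + 0.8))

    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall,
                rep.specificity, rep.f1) == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_degenerate_counts_undefined_not_zero(self):
        rep = metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert rep.precision is None
        assert rep.f1 is None
        assert rep.specificity == 1.0

    def test_sensitivity_is_recall_alias(self):
        rep = metrics(ConfusionCounts(tp=3, tn=1, fp=2, fn=1))
        assert rep.sensitivity is rep.recall

    def test_against_brute_force_oracle(self):
        """1000 random confusion tables vs pairwise enumeration."""
        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            labels = rng.integers(0, 2, n).tolist()
            preds = rng.integers(0, 2, n).tolist()
            (tp, tn, fp, fn), expected = brute_force_metrics(labels, preds)
            c = confusion(labels, preds)
            assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
            rep = metrics(c)
            for name, want in expected.items():
                got = getattr(rep, name)
                if want is None:
                    assert got is None
                else:
                    assert got == pytest.approx(want)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_perfect_inversion(self):
        assert auc([1, 2, 3, 4], [1, 1, 0, 0]) == 0.0

    def test_tie_gets_half_credit(self):
        assert auc([0.9, 0.8, 0.8, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)

    def test_single_class_undefined(self):
        assert auc([0.5, 0.6], [1, 1]) is None

    def test_exhaustive_small_cases(self):
        """All binary labelings of up to 8 scored items vs pair counting."""
        rng = np.random.default_rng(2)
        for n in range(2, 9):
            scores = np.round(rng.uniform(0, 1, n), 1)   # induces ties
            for labels in itertools.product([0, 1], repeat=n):
                expected = brute_force_auc(scores, labels)
                got = auc(scores, list(labels))
                if expected is None:
                    assert got is None
                else:
                    assert got == pytest.approx(expected)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, 60)
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


class TestAggregation:
    def test_identical_folds_zero_sd(self):
        reps = []
        for _ in range(5):
            rep = metrics(ConfusionCounts(8, 8, 2, 2))
            rep.auc = 0.9
            reps.append(rep)
        table = aggregate_folds(reps)
        assert np.allclose(table["sd"].astype(float), 0.0)

    def test_two_fold_mean_and_sd(self):
        reps = [evalrep.MetricsReport(accuracy=0.8),
                evalrep.MetricsReport(accuracy=0.9)]
        table = aggregate_folds(reps)
        row = table[table["metric"] == "Acc. (%)"].iloc[0]
        assert row["mean"] == pytest.approx(85.0)
        assert row["sd"] == pytest.approx(100 * 0.0707, abs=0.01)

    def test_table_schema(self):
        reps = [metrics(ConfusionCounts(5, 5, 0, 0))]
        reps[0].auc = 1.0
        table = aggregate_folds(reps)
        assert list(table["metric"]) == ["Acc. (%)", "F1 (%)", "AUC",
                                         "Sens. (%)", "Spec. (%)"]


class TestCalibration:
    def test_all_correct_fully_confident(self):
        p = np.tile([0.0, 1.0], (5, 1))
        cal = calibration_summary(p, [True] * 5)
        assert cal.correct_hist[-1] == 5
        assert cal.correct_hist[:-1].sum() == 0
        assert cal.mean_confidence_correct == 1.0

    def test_empty_incorrect_group_undefined(self):
        cal = calibration_summary(np.tile([0.1, 0.9], (3, 1)), [True] * 3)
        assert cal.mean_confidence_incorrect is None

    def test_histogram_covers_half_to_one(self):
        cal = calibration_summary(np.array([[0.45, 0.55], [0.05, 0.95]]),
                                  [True, False])
        assert cal.bin_edges[0] == 0.5 and cal.bin_edges[-1] == 1.0
        assert len(cal.correct_hist) == 10
        assert isinstance(cal, CalibrationSummary)
        assert cal.reliability["n"].sum() == 2


class TestConcentrationRules:
    def test_strong_fold_accuracies_reliable(self):
        accs = np.array([0.75, 0.77, 0.73, 0.76, 0.75])
        res = concentration_table({0.3: accs})
        row = res.table.iloc[0]
        t_expected = (accs.mean() - 0.5) / (accs.std(ddof=1) / np.sqrt(5))
        assert row["t_statistic"] == pytest.approx(t_expected)
        assert row["p_value"] < 1e-3
        assert row["status"] == "reliable detection"
        assert res.detection_threshold == 0.3

    def test_exact_chance_is_p_one(self):
        res = concentration_table({0.03: np.full(5, 0.5)})
        row = res.table.iloc[0]
        assert row["t_statistic"] == 0.0
        assert row["p_value"] == 1.0
        assert row["status"] == "at chance level"
        assert res.detection_threshold is None

    def test_threshold_is_lowest_qualifying_level(self):
        res = concentration_table({
            0.03: np.array([0.52, 0.48, 0.5, 0.51, 0.49]),
            0.1: np.array([0.61, 0.60, 0.62, 0.59, 0.60]),
            0.3: np.array([0.75, 0.77, 0.73, 0.76, 0.75]),
            1.0: np.array([0.87, 0.86, 0.88, 0.85, 0.86]),
        })
        assert res.detection_threshold == 0.3
        assert res.status(1.0) == "robust detection"
        assert res.status(0.1) == "marginal detection"


class TestEmbedding:
    def test_separated_clusters_high_silhouette(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(40, 16)) * 0.1
        b = rng.normal(size=(40, 16)) * 0.1 + 5.0
        feats = np.vstack([a, b])
        labels = np.array(["x"] * 40 + ["y"] * 40)
        emb = tsne_embedding(feats, labels, seed=0)
        assert emb.coords_2d.shape == (80, 2)
        assert emb.coords_3d.shape == (80, 3)
        assert emb.silhouette > 0.5

    def test_degenerate_features_flagged(self):
        feats = np.ones((20, 8))
        labels = np.array(["x", "y"] * 10)
        emb = tsne_embedding(feats, labels, seed=0)
        assert emb.silhouette is None

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(30, 10))
        labels = np.array(["x", "y", "z"] * 10)
        a = tsne_embedding(feats, labels, seed=42)
        b = tsne_embedding(feats, labels, seed=42)
        np.testing.assert_array_equal(a.coords_2d, b.coords_2d)


class TestLatency:
    def test_report_uses_exactly_the_timed_runs(self):
        model = models.build_attention_cnn(seed=0)
        table = latency_benchmark(model, batch_sizes=(1,), n_warmup=2,
                                  n_runs=10)
        row = table.iloc[0]
        assert row["n_timed_runs"] == 10
        assert row["latency_ms_mean"] > 0
        assert row["throughput_per_s"] == pytest.approx(
            1e3 / row["latency_ms_mean"])
        assert row["real_time_factor"] == pytest.approx(
            2000.0 / row["latency_ms_mean"])
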