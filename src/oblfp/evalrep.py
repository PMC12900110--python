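"""Metrics, calibration, per-odor and concentration analyses, embeddings.

Binary metrics take odor presence as the positive class:

* accuracy  = (TP + TN) / (TP + TN + FP + FN)
* precision = TP / (TP + FP)
* recall (= sensitivity) = TP / (TP + FN)
* specificity = TN / (TN + FP)
* F1 = harmonic mean of precision and recall

A metric with a zero denominator is reported as ``None`` (undefined, with
a logged reason), never as 0.  AUC is the Mann-Whitney rank statistic:
the probability that a random positive outscores a random negative, ties
counted half, which equals trapezoidal ROC integration.  Per-fold values
aggregate as mean +/- sample standard deviation.

The concentration analysis tests each level's five fold accuracies
against the 0.5 chance level with a two-sided one-sample t-test (df = 4);
the detection threshold is the lowest concentration with p < 0.001 and
accuracy > 70%.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CalibrationSummary",
    "ConcentrationResult",
    "EmbeddingResult",
    "confusion",
    "metrics",
    "auc",
    "aggregate_folds",
    "calibration_summary",
    "tsne_embedding",
    "latency_benchmark",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "specificity", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Eq-defined metric values for one evaluation; ``None`` = undefined."""

    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    specificity: float | None = None
    f1: float | None = None
    auc: float | None = None

    @property
    def sensitivity(self) -> float | None:
        """Sensitivity is the same quantity as recall (one number, two names)."""
        return self.recall

    def as_dict(self) -> dict:
        return {name: getattr(self, name)
                for name in (*METRIC_NAMES, "auc")}


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/TN/FP/FN with presence (1) as the positive class."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionCounts(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        logger.info("%s undefined: zero denominator", name)
        return None
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the five confusion-matrix metrics (AUC needs scores; see
    :func:`auc`)."""
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    recall = _ratio(c.tp, c.tp + c.fn, "recall")
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
        logger.info("f1 undefined")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy"),
        precision=precision,
        recall=recall,
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
        f1=f1,
    )


def auc(scores, labels) -> float | None:
    """Area under the ROC curve via the rank statistic: the probability
    that a random positive outranks a random negative, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        logger.info("auc undefined: single-class input")
        return None
    ranks = scipy.stats.rankdata(scores)
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aggregate_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    """Mean +/- sample SD per metric over folds (table layout:
    Acc. / F1 / AUC / Sens. / Spec.)."""
    rows = []
    for name, col in (("accuracy", "Acc. (%)"), ("f1", "F1 (%)"),
                      ("auc", "AUC"), ("recall", "Sens. (%)"),
                      ("specificity", "Spec. (%)")):
        vals = [getattr(r, name) for r in reports]
        defined = [v for v in vals if v is not None]
        scale = 1.0 if name == "auc" else 100.0
        mean = scale * float(np.mean(defined)) if defined else None
        sd = (scale * float(np.std(defined, ddof=1)) if len(defined) > 1
              else (0.0 if defined else None))
        rows.append({"metric": col, "mean": mean, "sd": sd,
                     "n_folds": len(defined)})
    return pd.DataFrame(rows)


@dataclass
class CalibrationSummary:
    """Confidence histogram (10 equal bins on [0.5, 1]) split by correctness,
    plus group mean confidences and binned reliability."""

    bin_edges: np.ndarray
    correct_hist: np.ndarray
    incorrect_hist: np.ndarray
    mean_confidence_correct: float | None
    mean_confidence_incorrect: float | None
    reliability: pd.DataFrame = field(repr=False, default=None)


def calibration_summary(p_ens: np.ndarray, correct) -> CalibrationSummary:
    """Summarize prediction confidence (max fused probability) by outcome."""
    p_ens = np.atleast_2d(np.asarray(p_ens, dtype=float))
    correct = np.asarray(correct, dtype=bool)
    conf = p_ens.max(axis=1)
    edges = np.linspace(0.5, 1.0, 11)
    hist_c = np.histogram(conf[correct], bins=edges)[0]
    hist_i = np.histogram(conf[~correct], bins=edges)[0]

    def _mean(group):
        if group.size == 0:
            logger.info("calibration group empty: mean undefined")
            return None
        return float(group.mean())

    # binned reliability: mean confidence vs empirical accuracy per bin
    idx = np.clip(np.digitize(conf, edges) - 1, 0, 9)
    rel_rows = []
    for b in range(10):
        mask = idx == b
        rel_rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "n": int(mask.sum()),
            "mean_confidence": float(conf[mask].mean()) if mask.any() else None,
            "empirical_accuracy": float(correct[mask].mean()) if mask.any() else None,
        })
    return CalibrationSummary(
        bin_edges=edges, correct_hist=hist_c, incorrect_hist=hist_i,
        mean_confidence_correct=_mean(conf[correct]),
        mean_confidence_incorrect=_mean(conf[~correct]),
        reliability=pd.DataFrame(rel_rows),
    )


@dataclass
class ConcentrationResult:
    """Per-concentration fold accuracies with t-tests against chance."""

    table: pd.DataFrame
    detection_threshold: float | None

    def status(self, concentration: float) -> str:
        row = self.table[self.table["concentration"] == concentration]
        if row.empty:
            raise KeyError(concentration)
        return row["status"].iloc[0]


def concentration_status(p_value: float, mean_accuracy: float) -> str:
    if p_value < 1e-3 and mean_accuracy > 0.85:
        return "robust detection"
    if p_value < 1e-3 and mean_accuracy > 0.70:
        return "reliable detection"
    if p_value < 0.05:
        return "marginal detection"
    return "at chance level"


def concentration_table(fold_accuracies: dict[float, np.ndarray]) -> ConcentrationResult:
    """Build the dose-response table from per-level fold accuracies.

    Each level's accuracies are tested against 0.5 with a two-sided
    one-sample t-test; the detection threshold is the lowest level with
    p < 0.001 and mean accuracy > 70%.
    """
    rows = []
    for conc in sorted(fold_accuracies):
        accs = np.asarray(fold_accuracies[conc], dtype=float)
        if np.allclose(accs, accs[0]):
            # zero variance: t-test degenerates; exact chance -> p = 1
            t_stat = 0.0 if np.isclose(accs[0], 0.5) else np.inf
            p_val = 1.0 if np.isclose(accs[0], 0.5) else 0.0
        else:
            t_stat, p_val = scipy.stats.ttest_1samp(accs, 0.5)
        mean_acc = float(accs.mean())
        rows.append({
            "concentration": conc,
            "mean_accuracy": mean_acc,
            "sd_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
            "t_statistic": float(t_stat),
            "p_value": float(p_val),
            "status": concentration_status(p_val, mean_acc),
        })
    table = pd.DataFrame(rows)
    detected = table[(table["p_value"] < 1e-3) & (table["mean_accuracy"] > 0.70)]
    threshold = float(detected["concentration"].min()) if len(detected) else None
    return ConcentrationResult(table=table, detection_threshold=threshold)


@dataclass
class EmbeddingResult:
    coords_2d: np.ndarray
    coords_3d: np.ndarray
    silhouette: float | None
    perplexity: float
    seed: int


def tsne_embedding(features: np.ndarray, labels, *, perplexity: float = 30.0,
                   seed: int = 42) -> EmbeddingResult:
    """2-D and 3-D t-SNE embeddings of trial feature vectors with a
    silhouette score over odorant-identity labels in the 2-D space."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    n = features.shape[0]
    perplexity = min(perplexity, max(1.0, (n - 1) / 3.0))
    degenerate = np.allclose(features.std(axis=0), 0.0)
    coords = {}
    for dim in (2, 3):
        tsne = TSNE(n_components=dim, perplexity=perplexity, random_state=seed,
                    init="pca" if not degenerate else "random")
        coords[dim] = tsne.fit_transform(features)
    sil = None
    if degenerate or len(np.unique(labels)) < 2:
        logger.info("silhouette undefined: degenerate features or single label")
    else:
        sil = float(silhouette_score(coords[2], labels))
    return EmbeddingResult(coords_2d=coords[2], coords_3d=coords[3],
                           silhouette=sil, perplexity=perplexity, seed=seed)


def per_odor_analysis(features, meta, config=None, odorants=None):
    """Per-odorant balanced binary runs; see :func:`oblfp.pipeline.per_odor_analysis`."""
    from .pipeline import per_odor_analysis as _impl
    return _impl(features, meta, config, odorants)


def concentration_analysis(features, meta, config=None):
    """Dose-response runs; see :func:`oblfp.pipeline.concentration_analysis`."""
    from .pipeline import concentration_analysis as _impl
    return _impl(features, meta, config)


def latency_benchmark(model, batch_sizes=(1, 64), *, n_warmup: int = 50,
                      n_runs: int = 200, trial_duration_ms: float = 2000.0,
                      input_shape=(32, 129)) -> pd.DataFrame:
    """Wall-clock inference timing: ``n_warmup`` discarded warm-up passes,
    then ``n_runs`` timed passes per batch size; reports mean +/- SD latency,
    throughput, and the real-time factor (trial duration / latency).

    Hardware-dependent; reported, never asserted in tests.
    """
    rng = np.random.default_rng(0)
    rows = []
    for bs in batch_sizes:
        x = rng.normal(size=(bs, *input_shape))
        for _ in range(n_warmup):
            model.predict(x)
        times = np.empty(n_runs)
        for i in range(n_runs):
            t0 = time.perf_counter()
            model.predict(x)
            times[i] = (time.perf_counter() - t0) * 1e3
        mean_ms = float(times.mean())
        rows.append({
            "batch_size": bs,
            "n_timed_runs": n_runs,
            "latency_ms_mean": mean_ms,
            "latency_ms_sd": float(times.std(ddof=1)),
            "throughput_per_s": bs * 1e3 / mean_ms,
            "real_time_factor": trial_duration_ms / mean_ms,
        })
    return pd.DataFrame(rows)
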