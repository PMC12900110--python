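"""End-to-end decoding runs: featurization, fold-wise ensemble training,
and the per-odor and concentration-ladder experiments.

For every cross-validation fold the robust scaler is fit on the fold's
training trials only, both ensemble members train under the one-cycle
policy with early stopping, and the fused predictions are evaluated on
the held-out test trials; test trials never influence scaler statistics,
model selection, or early stopping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import evalrep, preprocess, synthgen
from .dataio import CONTROL_NAME, TrialSet
from .models import build_attention_cnn, build_res_cnn
from .train import TrainConfig, TrainingHistory, ensemble_predict, make_folds, train_model

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CVResult",
    "featurize_trialset",
    "features_for_plan",
    "balanced_main_plan",
    "run_ensemble_cv",
    "per_odor_analysis",
    "concentration_analysis",
]


@dataclass
class PipelineConfig:
    """Settings for one cross-validated ensemble run."""

    train: TrainConfig = field(default_factory=TrainConfig)
    k: int = 5
    seed: int = 42
    collect_embeddings: bool = False


@dataclass
class CVResult:
    """Pooled test-set outputs of a k-fold ensemble run."""

    reports: list[evalrep.MetricsReport]
    fold_accuracies: np.ndarray
    labels: np.ndarray
    predictions: np.ndarray
    p_ens: np.ndarray
    test_fold: np.ndarray
    embeddings: np.ndarray | None
    histories: list[tuple[TrainingHistory, TrainingHistory]]

    @property
    def accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def pooled_auc(self) -> float | None:
        return evalrep.auc(self.p_ens[:, 1], self.labels)

    def summary(self) -> pd.DataFrame:
        return evalrep.aggregate_folds(self.reports)


def featurize_trialset(ts: TrialSet) -> np.ndarray:
    """PSD features for every trial, stacked ``(n_trials, channels, bins)``."""
    return np.stack([preprocess.featurize_trial(t).psd for t in ts.trials])


def features_for_plan(config: synthgen.SynthConfig,
                      plan: pd.DataFrame) -> np.ndarray:
    """Generate and featurize a plan's trials one at a time (constant
    memory: raw 30 kHz signals are discarded after spectral extraction)."""
    return np.stack([preprocess.featurize_trial(t).psd
                     for t in synthgen.iter_trials(config, plan)])


def balanced_main_plan(layout: synthgen.MainLayout, balance_seed: int) -> pd.DataFrame:
    """Class-balance the main layout on metadata alone.

    Under-samples the odor-presence majority to the control count before
    any signal is generated; counter-derived substreams make the selected
    trials identical to the same rows of the full layout.
    """
    plan = synthgen.trial_plan(layout)
    is_ctrl = plan["odorant"] == CONTROL_NAME
    n_ctrl, n_odor = int(is_ctrl.sum()), int((~is_ctrl).sum())
    if n_ctrl == 0 or n_odor == 0:
        raise ValueError("main layout must contain both classes")
    rng = np.random.default_rng(balance_seed)
    if n_odor > n_ctrl:
        keep = rng.choice(plan.index[~is_ctrl], size=n_ctrl, replace=False)
        plan = plan.loc[sorted(set(keep) | set(plan.index[is_ctrl]))]
    elif n_ctrl > n_odor:
        keep = rng.choice(plan.index[is_ctrl], size=n_odor, replace=False)
        plan = plan.loc[sorted(set(keep) | set(plan.index[~is_ctrl]))]
    return plan.reset_index(drop=True)


def run_ensemble_cv(features: np.ndarray, labels: np.ndarray,
                    config: PipelineConfig | None = None) -> CVResult:
    """Stratified k-fold ensemble run on featurized trials.

    ``labels``: 1 = odor presence, 0 = absence.  Returns pooled test-set
    predictions plus per-fold metric reports.
    """
    config = config or PipelineConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    idx = np.arange(n)
    folds = make_folds(idx, labels, k=config.k, seed=config.seed)

    predictions = np.full(n, -1, dtype=int)
    p_ens_all = np.zeros((n, 2))
    test_fold = np.full(n, -1, dtype=int)
    embeddings = np.zeros((n, 192 + 128)) if config.collect_embeddings else None
    reports, accs, histories = [], [], []

    for fold in folds:
        tr, va, te = fold.train_ids, fold.val_ids, fold.test_ids
        scaler = preprocess.fit_scaler(features[tr])
        x_tr = preprocess.apply_scaler(features[tr], scaler)
        x_va = preprocess.apply_scaler(features[va], scaler)
        x_te = preprocess.apply_scaler(features[te], scaler)
        data = {"X_train": x_tr, "y_train": labels[tr],
                "X_val": x_va, "y_val": labels[va]}

        member_probs, member_embs = [], []
        for member, build in enumerate((build_attention_cnn, build_res_cnn)):
            seed = (config.seed * 1009 + fold.fold_index * 13 + member) % (2**31)
            model = build(seed=seed)
            tcfg = replace(config.train, seed=seed)
            model, hist = train_model(model, data, tcfg,
                                      rng=np.random.default_rng(seed))
            out = model.predict(x_te)
            member_probs.append(out.probabilities)
            member_embs.append(model.embedding)
            if member == 0:
                fold_hists = [hist]
            else:
                fold_hists.append(hist)
        histories.append(tuple(fold_hists))

        fused = ensemble_predict(member_probs[0], member_probs[1])
        predictions[te] = fused.labels
        p_ens_all[te] = fused.p_ens
        test_fold[te] = fold.fold_index
        if embeddings is not None:
            embeddings[te] = np.concatenate(member_embs, axis=1)

        report = evalrep.metrics(evalrep.confusion(labels[te], fused.labels))
        report.auc = evalrep.auc(fused.p_ens[:, 1], labels[te])
        reports.append(report)
        accs.append(report.accuracy)
        # soft complementarity check: fusion should not fall far below
        # the weaker member (logged, never asserted — small folds are noisy)
        member_accs = [float((p.argmax(axis=1) == labels[te]).mean())
                       for p in member_probs]
        logger.info(
            "fold %d: ensemble %.3f, attention %.3f, residual %.3f%s",
            fold.fold_index, report.accuracy, member_accs[0], member_accs[1],
            "  [ensemble below weaker member]"
            if report.accuracy < min(member_accs) else "")

    return CVResult(reports=reports, fold_accuracies=np.array(accs),
                    labels=labels, predictions=predictions, p_ens=p_ens_all,
                    test_fold=test_fold, embeddings=embeddings,
                    histories=histories)


def _balanced_binary(features: np.ndarray, pos_mask: np.ndarray,
                     neg_mask: np.ndarray, seed: int):
    """Under-sample the larger of two groups to the smaller's size."""
    pos_idx = np.flatnonzero(pos_mask)
    neg_idx = np.flatnonzero(neg_mask)
    rng = np.random.default_rng(seed)
    m = min(len(pos_idx), len(neg_idx))
    if len(pos_idx) > m:
        pos_idx = np.sort(rng.choice(pos_idx, size=m, replace=False))
    if len(neg_idx) > m:
        neg_idx = np.sort(rng.choice(neg_idx, size=m, replace=False))
    sel = np.concatenate([neg_idx, pos_idx])
    y = np.concatenate([np.zeros(len(neg_idx), int), np.ones(len(pos_idx), int)])
    return features[sel], y


def per_odor_analysis(features: np.ndarray, meta: pd.DataFrame,
                      config: PipelineConfig | None = None,
                      odorants=None) -> pd.DataFrame:
    """Separate balanced binary runs: each odorant against the control.

    ``meta`` must carry an ``odorant`` column aligned with ``features``.
    Returns one row per odorant with fold-mean accuracy +/- SD.
    """
    config = config or PipelineConfig()
    odor_col = meta["odorant"].to_numpy()
    ctrl_mask = odor_col == CONTROL_NAME
    if odorants is None:
        odorants = [o for o in pd.unique(odor_col) if o != CONTROL_NAME]
    rows = []
    for odor in odorants:
        mask = odor_col == odor
        if not mask.any():
            logger.warning("odorant '%s' absent from the set; skipped", odor)
            continue
        x, y = _balanced_binary(features, mask, ctrl_mask, config.seed)
        res = run_ensemble_cv(x, y, config)
        rows.append({
            "odorant": odor,
            "n_trials": int(len(y)),
            "accuracy_mean": res.accuracy,
            "accuracy_sd": float(res.fold_accuracies.std(ddof=1)),
        })
    return pd.DataFrame(rows)


def concentration_analysis(features: np.ndarray, meta: pd.DataFrame,
                           config: PipelineConfig | None = None
                           ) -> evalrep.ConcentrationResult:
    """Dose-response: one balanced binary run per concentration level
    against the controls, then fold accuracies vs the 0.5 chance level."""
    config = config or PipelineConfig()
    odor_col = meta["odorant"].to_numpy()
    conc_col = meta["concentration"].to_numpy(dtype=float)
    ctrl_mask = odor_col == CONTROL_NAME
    levels = sorted(c for c in np.unique(conc_col[~ctrl_mask]) if c > 0)
    fold_accs = {}
    for conc in levels:
        mask = (~ctrl_mask) & np.isclose(conc_col, conc)
        x, y = _balanced_binary(features, mask, ctrl_mask, config.seed)
        res = run_ensemble_cv(x, y, config)
        fold_accs[float(conc)] = res.fold_accuracies
    return evalrep.concentration_table(fold_accs)
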