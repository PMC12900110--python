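"""Cross-validation folds, learning-rate schedules, training loop, fusion.

Five-fold stratified cross-validation: each fold holds out ~20% of trials
for testing and carves 10% of the remaining training portion into a
validation set.  Models train with AdamW (decoupled weight decay),
either a cosine-warm-restarts schedule (T0 = 10 epochs, Tmult = 2, used
for standalone model evaluation) or a one-cycle policy (used for the two
ensemble members), and early stopping on validation loss with a minimum
improvement delta; the best-validation-loss checkpoint is restored.

Ensemble fusion is parameter-free late fusion: the arithmetic mean of the
two members' softmax probabilities, with the odor label assigned iff the
fused odor-presence probability strictly exceeds 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "EnsembleOutput",
    "TrainingHistory",
    "EarlyStopper",
    "make_folds",
    "schedule_lr",
    "train_model",
    "ensemble_predict",
]

# class order fixed everywhere: index 0 = absence, 1 = presence
ABSENCE, PRESENCE = 0, 1


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError(f"fold {self.fold_index}: overlapping id sets")


@dataclass
class TrainConfig:
    lr0: float = 5e-4
    weight_decay: float = 1e-4
    max_epochs: int = 150
    schedule: str = "one_cycle"          # or "cosine_warm_restarts"
    t0: int = 10
    t_mult: int = 2
    patience: int = 15
    min_delta: float = 1e-3
    batch_size: int = 32
    seed: int = 42

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("need 0 < patience < max_epochs")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based epoch of the restored checkpoint
    stopped_epoch: int = 0       # 1-based last epoch that ran


def make_folds(trial_ids, labels, k: int = 5, seed: int = 42) -> list[FoldSplit]:
    """Stratified k-fold partition; within each fold the training portion is
    split 90/10 (stratified) into train and validation."""
    trial_ids = np.asarray(trial_ids)
    labels = np.asarray(labels)
    if trial_ids.shape != labels.shape:
        raise ValueError("trial_ids and labels must align")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratification error: a class has {counts.min()} < k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    n_classes = len(np.unique(labels))
    folds = []
    for i, (rest_idx, test_idx) in enumerate(skf.split(trial_ids, labels)):
        # 10% of the training portion, but at least one trial per class
        val_n = max(n_classes, int(np.ceil(0.1 * len(rest_idx))))
        train_idx, val_idx = train_test_split(
            rest_idx, test_size=val_n, random_state=seed + i,
            stratify=labels[rest_idx])
        folds.append(FoldSplit(
            fold_index=i,
            train_ids=trial_ids[np.sort(train_idx)],
            val_ids=trial_ids[np.sort(val_idx)],
            test_ids=trial_ids[np.sort(test_idx)],
        ))
    return folds


def schedule_lr(config: TrainConfig, epoch: int) -> float:
    """Learning rate at a (0-based) epoch under the configured schedule.

    Cosine warm restarts: within a cycle of length ``T_i`` (``T_0`` = t0,
    ``T_{i+1} = t_mult * T_i``), ``lr = lr0/2 * (1 + cos(pi * t / T_i))``
    with zero floor; the rate snaps back to ``lr0`` at each restart.

    One-cycle: cosine ramp from ``lr0/25`` up to ``lr0`` over the first 30%
    of ``max_epochs``, then cosine anneal down to ``lr0/1e4``.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if config.schedule == "cosine_warm_restarts":
        t, ti = epoch, config.t0
        while t >= ti:
            t -= ti
            ti *= config.t_mult
        return 0.5 * config.lr0 * (1.0 + math.cos(math.pi * t / ti))
    if config.schedule == "one_cycle":
        warm = max(1, round(0.3 * config.max_epochs))
        lo, final = config.lr0 / 25.0, config.lr0 / 1e4
        if epoch <= warm:
            frac = epoch / warm
            return lo + (config.lr0 - lo) * 0.5 * (1.0 - math.cos(math.pi * frac))
        frac = min(1.0, (epoch - warm) / max(1, config.max_epochs - 1 - warm))
        return final + (config.lr0 - final) * 0.5 * (1.0 + math.cos(math.pi * frac))
    raise ValueError(f"unknown schedule '{config.schedule}'")


class EarlyStopper:
    """Validation-loss early stopping with a minimum improvement delta.

    ``update`` returns ``(improved, stop)``: ``improved`` marks a new best
    (checkpoint now), ``stop`` fires once no improvement of at least
    ``min_delta`` has been seen for ``patience`` consecutive epochs.
    """

    def __init__(self, patience: int, min_delta: float):
        self.patience = patience
        self.min_delta = min_delta
        self.best_loss = math.inf
        self.best_epoch = 0
        self.count = 0
        self.epoch = 0

    def update(self, loss: float) -> tuple[bool, bool]:
        self.epoch += 1
        if self.best_loss - loss >= self.min_delta:
            self.best_loss = loss
            self.best_epoch = self.epoch
            self.count = 0
            return True, False
        self.count += 1
        return False, self.count >= self.patience


def _eval_loss(model: nn.Module, x: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    model.eval()
    total, n = 0.0, len(y)
    for i in range(0, n, batch_size):
        logits = model.forward(x[i: i + batch_size])
        loss, _ = nn.cross_entropy(logits, y[i: i + batch_size])
        total += loss * len(y[i: i + batch_size])
    return total / n


def train_model(model: nn.Module, data: dict, config: TrainConfig,
                rng: np.random.Generator | None = None):
    """Train with AdamW + schedule + early stopping; restore the best
    validation-loss checkpoint.

    ``data`` holds arrays ``X_train, y_train, X_val, y_val`` (features must
    already be scaled with statistics fit on the training portion only).
    Returns ``(model, TrainingHistory)``.
    """
    x_tr, y_tr = np.asarray(data["X_train"]), np.asarray(data["y_train"])
    x_va, y_va = np.asarray(data["X_val"]), np.asarray(data["y_val"])
    if len(y_va) == 0:
        raise ValueError("validation set is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    opt = nn.AdamW(model.parameters(), lr=config.lr0,
                   weight_decay=config.weight_decay)
    hist = TrainingHistory()
    stopper = EarlyStopper(config.patience, config.min_delta)
    best_state = model.get_state()

    for epoch in range(config.max_epochs):
        opt.lr = schedule_lr(config, epoch)
        model.train()
        perm = rng.permutation(len(y_tr))
        epoch_loss = 0.0
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i: i + config.batch_size]
            model.zero_grad()
            logits = model.forward(x_tr[idx])
            loss, dlogits = nn.cross_entropy(logits, y_tr[idx])
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        val_loss = _eval_loss(model, x_va, y_va, config.batch_size)
        hist.train_loss.append(epoch_loss / len(y_tr))
        hist.val_loss.append(val_loss)
        hist.lr.append(opt.lr)
        hist.stopped_epoch = epoch + 1
        improved, stop = stopper.update(val_loss)
        if improved:
            best_state = model.get_state()
            hist.best_epoch = stopper.best_epoch
        if stop:
            break
    model.set_state(best_state)
    model.eval()
    return model, hist


@dataclass
class EnsembleOutput:
    """Fused probabilities ``p_ens = (p_att + p_res) / 2`` and hard labels
    (presence iff ``p_ens[presence] > 0.5``; a tie maps to absence)."""

    p_ens: np.ndarray

    def __post_init__(self):
        self.p_ens = np.atleast_2d(np.asarray(self.p_ens, dtype=float))

    @property
    def labels(self) -> np.ndarray:
        return (self.p_ens[:, PRESENCE] > 0.5).astype(int)

    @property
    def confidence(self) -> np.ndarray:
        return self.p_ens.max(axis=1)


def ensemble_predict(p_att: np.ndarray, p_res: np.ndarray,
                     tol: float = 1e-6) -> EnsembleOutput:
    """Parameter-free late fusion: arithmetic mean of two softmax outputs."""
    p_att = np.atleast_2d(np.asarray(p_att, dtype=float))
    p_res = np.atleast_2d(np.asarray(p_res, dtype=float))
    if p_att.shape != p_res.shape or p_att.shape[1] != 2:
        raise ValueError("probability inputs must both be (n, 2)")
    for name, p in (("p_att", p_att), ("p_res", p_res)):
        if np.any(p < -tol) or np.any(np.abs(p.sum(axis=1) - 1.0) > tol):
            raise ValueError(f"{name} rows must be probability vectors")
    return EnsembleOutput(p_ens=(p_att + p_res) / 2.0)
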