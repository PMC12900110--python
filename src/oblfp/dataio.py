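"""Trial containers, HDF5 persistence, labeling and class balancing.

A :class:`TrialRecording` is one multichannel LFP trial (channels x
samples, microvolts) with its stimulus metadata; a :class:`TrialSet` is an
ordered collection sharing channel count and sampling rate.  Binary labels
follow a :class:`LabelScheme`: trials whose odorant is in the control set
are odor-absence, everything else odor-presence.  Class balancing
randomly under-samples the majority class, without replacement, down to
the minority count — on the canonical layout this turns 2013 presence /
336 absence trials into a balanced 672-trial set.

On disk a trial set is an HDF5 file (one 3-D ``trials x channels x
samples`` array per sampling-rate group) plus a human-inspectable CSV
metadata sidecar ``<stem>.meta.csv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_NAME",
    "CLASS_ABSENCE",
    "CLASS_PRESENCE",
    "CLASS_UNASSIGNED",
    "TrialRecording",
    "TrialSet",
    "LabelScheme",
    "FormatError",
    "BalancingError",
    "write_trialset",
    "read_trialset",
    "assign_labels",
    "balance_classes",
    "read_crcns",
]

CONTROL_NAME = "mineral oil"
CLASS_ABSENCE = "absence"
CLASS_PRESENCE = "presence"
CLASS_UNASSIGNED = "unassigned"


class FormatError(ValueError):
    pass


class BalancingError(ValueError):
    pass


@dataclass
class TrialRecording:
    """One trial: ``n_channels x n_samples`` signal (microvolts) plus metadata."""

    trial_id: str
    signal: np.ndarray
    fs: float
    odorant_name: str
    concentration: float = 0.0
    subject_id: str = ""
    class_label: str = CLASS_UNASSIGNED

    def __post_init__(self):
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise FormatError(f"trial {self.trial_id}: signal must be 2-D")
        if not np.isfinite(self.signal).all():
            raise FormatError(f"trial {self.trial_id}: non-finite signal values")
        if self.fs <= 0:
            raise FormatError(f"trial {self.trial_id}: fs must be positive")
        if self.concentration < 0:
            raise FormatError(f"trial {self.trial_id}: negative concentration")
        if self.class_label not in (CLASS_ABSENCE, CLASS_PRESENCE, CLASS_UNASSIGNED):
            raise FormatError(f"trial {self.trial_id}: bad class label")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


class TrialSet:
    """Ordered collection of trials sharing channel count and sampling rate."""

    def __init__(self, trials: list[TrialRecording]):
        ids = [t.trial_id for t in trials]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate trial ids: {dupes[:5]}")
        if trials:
            c0, fs0 = trials[0].n_channels, trials[0].fs
            for t in trials:
                if t.n_channels != c0 or t.fs != fs0:
                    raise FormatError(
                        f"trial {t.trial_id}: channel count / fs mismatch")
        self.trials = list(trials)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, trial_id: str) -> TrialRecording:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(trial_id)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_id": [t.trial_id for t in self.trials],
            "odorant": [t.odorant_name for t in self.trials],
            "concentration": [t.concentration for t in self.trials],
            "subject": [t.subject_id for t in self.trials],
            "class": [t.class_label for t in self.trials],
        })

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.trials:
            counts[t.class_label] = counts.get(t.class_label, 0) + 1
        return counts

    def subset(self, trial_ids) -> "TrialSet":
        """Trials with the given ids, preserving this set's order."""
        wanted = set(trial_ids)
        missing = wanted - {t.trial_id for t in self.trials}
        if missing:
            raise KeyError(f"unknown trial ids: {sorted(missing)[:5]}")
        return TrialSet([t for t in self.trials if t.trial_id in wanted])


@dataclass
class LabelScheme:
    """Odorant names mapping to odor-absence; all others are presence."""

    control_names: frozenset[str] = field(
        default_factory=lambda: frozenset({CONTROL_NAME}))

    def __post_init__(self):
        self.control_names = frozenset(self.control_names)
        if not self.control_names:
            raise ValueError("control_names must be non-empty")

    def label(self, odorant_name: str) -> str:
        return CLASS_ABSENCE if odorant_name in self.control_names else CLASS_PRESENCE


# ---------------------------------------------------------------------------
# persistence


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def write_trialset(ts: TrialSet, path: str | Path) -> None:
    """Write signals to HDF5 and metadata to a CSV sidecar.

    Signals are grouped by sampling rate; within a group all trials share
    one 3-D array for columnar access.  ``read_trialset(write_trialset(ts))``
    reproduces signals bit-exactly and metadata field-for-field.
    """
    path = Path(path)
    meta = ts.metadata
    meta["fs"] = [t.fs for t in ts.trials]
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "oblfp-trialset-v1"
        by_fs: dict[float, list[TrialRecording]] = {}
        for t in ts.trials:
            by_fs.setdefault(t.fs, []).append(t)
        for gi, (fs, trials) in enumerate(sorted(by_fs.items())):
            grp = f.create_group(f"fs_{gi}")
            grp.attrs["fs"] = fs
            grp.create_dataset(
                "signals", data=np.stack([t.signal for t in trials]))
            grp.create_dataset(
                "trial_id",
                data=np.array([t.trial_id for t in trials], dtype="S"))
    meta.to_csv(_meta_path(path), index=False)


def read_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mp = _meta_path(path)
    if not mp.exists():
        raise FormatError(f"metadata sidecar missing: {mp}")
    meta = pd.read_csv(mp, dtype={"trial_id": str}, keep_default_na=False)
    signals: dict[str, tuple[np.ndarray, float]] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            grp = f[name]
            fs = float(grp.attrs["fs"])
            ids = [s.decode() for s in grp["trial_id"][()]]
            data = grp["signals"][()]
            if len(ids) != data.shape[0]:
                raise FormatError(f"group {name}: id/array count mismatch")
            for i, tid in enumerate(ids):
                signals[tid] = (data[i], fs)
    trials = []
    for row in meta.to_dict("records"):
        tid = str(row["trial_id"])
        if tid not in signals:
            raise FormatError(
                f"metadata row for trial '{tid}' has no signal array")
        sig, fs = signals.pop(tid)
        trials.append(TrialRecording(
            trial_id=tid, signal=sig, fs=fs,
            odorant_name=str(row["odorant"]),
            concentration=float(row["concentration"]),
            subject_id=str(row["subject"]),
            class_label=str(row.get("class") or CLASS_UNASSIGNED),
        ))
    if signals:
        raise FormatError(
            f"signal arrays without metadata rows: {sorted(signals)[:5]}")
    return TrialSet(trials)


# ---------------------------------------------------------------------------
# labeling and balancing


def assign_labels(ts: TrialSet, scheme: LabelScheme | None = None) -> TrialSet:
    """Assign binary class labels from odorant names (pure metadata op)."""
    scheme = scheme or LabelScheme()
    return TrialSet([replace(t, class_label=scheme.label(t.odorant_name))
                     for t in ts.trials])


def balance_classes(ts: TrialSet, seed: int) -> TrialSet:
    """Random under-sampling, without replacement, of the majority class.

    Every minority-class trial is kept; the majority class is subsampled to
    the minority count.  The returned set preserves the original trial
    order.  Signals are untouched.
    """
    by_class: dict[str, list[str]] = {}
    for t in ts.trials:
        by_class.setdefault(t.class_label, []).append(t.trial_id)
    if set(by_class) != {CLASS_ABSENCE, CLASS_PRESENCE}:
        raise BalancingError(
            f"need both classes present, got {sorted(by_class)}")
    minority, majority = sorted(by_class.values(), key=len)
    if len(minority) == len(majority):
        return TrialSet(list(ts.trials))
    rng = np.random.default_rng(seed)
    kept = set(minority)
    kept.update(rng.choice(majority, size=len(minority), replace=False))
    return ts.subset(kept)


def read_crcns(path: str | Path) -> TrialSet:  # pragma: no cover - stub
    """Adapter for the original public dataset's file layout (unimplemented;
    the recordings require an external download)."""
    raise NotImplementedError(
        "ingestion of the original repository layout is not implemented; "
        "use the synthetic generator or the native container format")
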