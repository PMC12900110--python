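"""Decoder architectures for 32-channel x 129-bin PSD inputs.

Two compact 1-D convolutional classifiers share the binary odor-presence
head: an attention-based network (multi-scale branches, squeeze-and-
excitation channel attention, CBAM-style spatial attention) and a residual
network (squeeze-and-excitation residual blocks).  Under-specified stem
hyperparameters are pinned down by the published trainable-parameter
totals, which act as an architecture checksum:

* AttentionCNN: 155,104 trainable parameters (155.1 K)
* ResCNN:       306,274 trainable parameters (306.3 K)
* ensemble sum: 461,378 trainable parameters (461.4 K)

Input feature maps are ``(channels, frequency bins)``; the convolutional
"temporal" axis is the frequency-bin axis of the Welch PSD.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from . import nn

__all__ = [
    "FeatureMap",
    "SEParams",
    "ArchitectureSpec",
    "ClassifierOutput",
    "AttentionCNN",
    "ResCNN",
    "squeeze_excitation",
    "spatial_attention",
    "residual_block",
    "build_attention_cnn",
    "build_res_cnn",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
    "ARCHITECTURES",
]

N_INPUT_CHANNELS = 32
N_INPUT_BINS = 129


@dataclass
class FeatureMap:
    """A ``C x T`` feature map (channels x positions)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("feature map must be a C x T matrix with C,T >= 1")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def length(self) -> int:
        return self.values.shape[1]


@dataclass
class SEParams:
    """Weights of the squeeze-and-excitation bottleneck.

    ``w1`` maps channels to the reduced representation (``C/r x C``) and
    ``w2`` maps back (``C x C/r``); biases are optional.
    """

    w1: np.ndarray
    w2: np.ndarray
    r: int = 16
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        c = self.w1.shape[1]
        if c % self.r != 0 or self.w1.shape[0] != c // self.r:
            raise ValueError(
                f"reduction ratio {self.r} inconsistent with W1 shape {self.w1.shape}"
            )
        if self.w2.shape != (c, c // self.r):
            raise ValueError(f"W2 shape {self.w2.shape} inconsistent with W1")


@dataclass
class ArchitectureSpec:
    name: str = "attention_cnn"
    input_channels: int = N_INPUT_CHANNELS
    input_length: int = N_INPUT_BINS
    se_reduction: int = 16
    seed: int = 42
    extra: dict = field(default_factory=dict)


@dataclass
class ClassifierOutput:
    """Logits ``m(x)`` and softmax probabilities ``p(x)`` of a classifier.

    Class order is fixed throughout: index 0 = odor absence, 1 = presence.
    """

    logits: np.ndarray

    def __post_init__(self):
        self.logits = np.atleast_2d(np.asarray(self.logits, dtype=float))

    @property
    def probabilities(self) -> np.ndarray:
        return nn.softmax(self.logits)

    @property
    def predictions(self) -> np.ndarray:
        """Predicted labels: presence iff p(presence) > 0.5 (ties -> absence)."""
        return (self.probabilities[:, 1] > 0.5).astype(int)


# ---------------------------------------------------------------------------
# functional single-map operations


def squeeze_excitation(u: FeatureMap | np.ndarray, params: SEParams) -> np.ndarray:
    """Apply squeeze-and-excitation recalibration to one ``C x T`` map.

    ``z_c = (1/T) sum_t u_c(t)``; ``s = sigmoid(W2 relu(W1 z))``;
    row ``c`` of the output is ``s_c`` times row ``c`` of the input.
    """
    u = u.values if isinstance(u, FeatureMap) else np.asarray(u, dtype=float)
    c = u.shape[0]
    if params.w1.shape[1] != c:
        raise ValueError(f"params expect {params.w1.shape[1]} channels, map has {c}")
    mod = nn.SqueezeExcitation(c, r=params.r, bias=params.b1 is not None,
                               rng=np.random.default_rng(0))
    mod.w1.data[...] = params.w1
    mod.w2.data[...] = params.w2
    if params.b1 is not None:
        mod.b1.data[...] = params.b1
        mod.b2.data[...] = params.b2
    return mod.eval().forward(u[None])[0]


def spatial_attention(u: FeatureMap | np.ndarray,
                      weight: np.ndarray | None = None,
                      bias: float | None = None) -> np.ndarray:
    """Apply CBAM-style spatial attention to one ``C x T`` map.

    The mask at position ``t`` is ``sigmoid(conv_k7([mean_c u(t); max_c u(t)]))``
    and multiplies every channel at ``t``.  ``weight`` is the ``(1, 2, k)``
    convolution kernel (random fan-in-scaled default when omitted).
    """
    u = u.values if isinstance(u, FeatureMap) else np.asarray(u, dtype=float)
    if weight is None:
        weight = np.random.default_rng(0).uniform(-1, 1, size=(1, 2, 7)) / np.sqrt(14)
    weight = np.asarray(weight, dtype=float)
    mod = nn.SpatialAttention(k=weight.shape[2], bias=bias is not None,
                              rng=np.random.default_rng(0))
    mod.conv.weight.data[...] = weight
    if bias is not None:
        mod.conv.bias.data[...] = bias
    return mod.eval().forward(u[None])[0]


def residual_block(u: FeatureMap | np.ndarray, width: int, *,
                   block: nn.ResidualBlock | None = None,
                   seed: int = 0) -> np.ndarray:
    """Run one ``C x T`` map through a squeeze-and-excitation residual block.

    A freshly initialized block (evaluation mode, so batch-norm uses its
    unit running statistics) is built unless ``block`` is supplied.  The
    shortcut is the identity when the input width equals ``width`` and a
    1x1-convolution projection otherwise.
    """
    u = u.values if isinstance(u, FeatureMap) else np.asarray(u, dtype=float)
    if block is None:
        r = 16 if width % 16 == 0 else (math.gcd(width, 16) or 1)
        block = nn.ResidualBlock(u.shape[0], width, r=r,
                                 rng=np.random.default_rng(seed))
    elif block.conv1.cin != u.shape[0]:
        raise ValueError("block input width does not match the feature map")
    return block.eval().forward(u[None])[0]


# ---------------------------------------------------------------------------
# full architectures


class _Net(nn.Module):
    """Common plumbing: batched forward to logits plus a penultimate hook."""

    name = "net"

    def predict(self, x: np.ndarray) -> ClassifierOutput:
        """Evaluation-mode forward pass on ``(N, C, T)`` or ``(C, T)`` input."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        was_training = self.training
        self.eval()
        out = ClassifierOutput(self.forward(x))
        self.train(was_training)
        return out

    @property
    def embedding(self) -> np.ndarray:
        """Post-global-average-pool feature vectors from the last forward."""
        return self._embedding


class AttentionCNN(_Net):
    """Multi-scale attention classifier.

    maxpool s2 -> [Conv1D 32->48 k5, BN, ReLU, maxpool s4]
    -> [Conv1D 48->128 k3, BN, ReLU, maxpool s4]
    -> three parallel Conv1D branches (k 1/3/5, 64 filters each) -> concat 192
    -> squeeze-and-excitation (r=16) -> spatial attention -> global avg pool
    -> dropout 0.3 -> FC 256 + ReLU -> dropout 0.5 -> linear 2.

    Pooling chain over the bin axis: 129 -> 64 -> 16 -> 4.
    """

    name = "attention_cnn"

    def __init__(self, spec: ArchitectureSpec | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        spec = spec or ArchitectureSpec(name=self.name)
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        self.spec = spec
        cin = spec.input_channels
        self.stem = self.add(nn.Sequential(
            nn.MaxPool1d(2),
            nn.Conv1d(cin, 48, 5, rng=rng), nn.BatchNorm1d(48), nn.ReLU(),
            nn.MaxPool1d(4),
            nn.Conv1d(48, 128, 3, rng=rng), nn.BatchNorm1d(128), nn.ReLU(),
            nn.MaxPool1d(4),
        ))
        self.branches = [self.add(nn.Conv1d(128, 64, k, rng=rng)) for k in (1, 3, 5)]
        self.se = self.add(nn.SqueezeExcitation(192, r=spec.se_reduction, rng=rng))
        self.sa = self.add(nn.SpatialAttention(k=7, rng=rng))
        self.gap = self.add(nn.GlobalAvgPool1d())
        self.head = self.add(nn.Sequential(
            nn.Dropout(0.3, rng),
            nn.Linear(192, 256, rng=rng), nn.ReLU(),
            nn.Dropout(0.5, rng),
            nn.Linear(256, 2, rng=rng),
        ))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} input channels, got {x.shape[1]}")
        h = self.stem(x)
        h = np.concatenate([b(h) for b in self.branches], axis=1)
        h = self.sa(self.se(h))
        h = self.gap(h)
        self._embedding = h
        return self.head(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.gap.backward(self.head.backward(dlogits))
        dh = self.se.backward(self.sa.backward(dh))
        parts = np.split(dh, 3, axis=1)
        dstem = sum(b.backward(p) for b, p in zip(self.branches, parts))
        return self.stem.backward(dstem)


class ResCNN(_Net):
    """Residual classifier with squeeze-and-excitation residual blocks.

    maxpool s2 -> Conv1D 32->32 (k7, stride 2) + BN + ReLU -> maxpool s4
    -> three 64-channel SE-residual blocks (the first projects 32 -> 64)
    -> Conv1D 64->128 (k3) + BN + ReLU -> maxpool s2
    -> two 128-channel SE-residual blocks -> global avg pool
    -> dropout 0.4 -> linear 2.
    """

    name = "res_cnn"

    def __init__(self, spec: ArchitectureSpec | None = None, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        spec = spec or ArchitectureSpec(name=self.name)
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        self.spec = spec
        r = spec.se_reduction
        self.body = self.add(nn.Sequential(
            nn.MaxPool1d(2),
            nn.Conv1d(spec.input_channels, 32, 7, stride=2, rng=rng),
            nn.BatchNorm1d(32), nn.ReLU(),
            nn.MaxPool1d(4),
            nn.ResidualBlock(32, 64, r=r, rng=rng),
            nn.ResidualBlock(64, 64, r=r, rng=rng),
            nn.ResidualBlock(64, 64, r=r, rng=rng),
            nn.Conv1d(64, 128, 3, rng=rng), nn.BatchNorm1d(128), nn.ReLU(),
            nn.MaxPool1d(2),
            nn.ResidualBlock(128, 128, r=r, rng=rng),
            nn.ResidualBlock(128, 128, r=r, rng=rng),
        ))
        self.gap = self.add(nn.GlobalAvgPool1d())
        self.head = self.add(nn.Sequential(
            nn.Dropout(0.4, rng),
            nn.Linear(128, 2, rng=rng),
        ))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected {self.spec.input_channels} input channels, got {x.shape[1]}")
        h = self.gap(self.body(x))
        self._embedding = h
        return self.head(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.body.backward(self.gap.backward(self.head.backward(dlogits)))


# ---------------------------------------------------------------------------
# registry, counting, checkpoints


def build_attention_cnn(spec: ArchitectureSpec | None = None, *,
                        seed: int | None = None) -> AttentionCNN:
    if seed is not None:
        spec = spec or ArchitectureSpec(name="attention_cnn")
        spec.seed = seed
    return AttentionCNN(spec)


def build_res_cnn(spec: ArchitectureSpec | None = None, *,
                  seed: int | None = None) -> ResCNN:
    if seed is not None:
        spec = spec or ArchitectureSpec(name="res_cnn")
        spec.seed = seed
    return ResCNN(spec)


def _baseline_stub(name: str) -> Callable:
    def _build(*args, **kwargs):
        raise NotImplementedError(
            f"baseline architecture '{name}' is a registry stub; only the two "
            "ensemble members are implemented")
    return _build


ARCHITECTURES: dict[str, Callable] = {
    "attention_cnn": build_attention_cnn,
    "res_cnn": build_res_cnn,
    # comparison-harness extensibility hooks, intentionally unimplemented
    "vanilla_cnn": _baseline_stub("vanilla_cnn"),
    "deep_cnn": _baseline_stub("deep_cnn"),
    "dilated_cnn": _baseline_stub("dilated_cnn"),
    "wide_cnn": _baseline_stub("wide_cnn"),
    "shallow_cnn": _baseline_stub("shallow_cnn"),
}


def build_model(name: str, spec: ArchitectureSpec | None = None, *,
                seed: int | None = None) -> _Net:
    if name not in ARCHITECTURES:
        raise KeyError(f"unknown architecture '{name}'; known: {sorted(ARCHITECTURES)}")
    return ARCHITECTURES[name](spec, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


def save_checkpoint(model: _Net, path: str | Path) -> None:
    """Serialize parameters and batch-norm buffers plus a text manifest."""
    path = Path(path)
    arrays = model.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrays)
    manifest = {
        "architecture": model.name,
        "n_trainable_parameters": count_parameters(model),
        "input_channels": model.spec.input_channels,
        "input_length": model.spec.input_length,
        "seed": model.spec.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(model: _Net, path: str | Path) -> _Net:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    if manifest["architecture"] != model.name:
        raise ValueError(
            f"checkpoint is for '{manifest['architecture']}', model is '{model.name}'")
    with np.load(path.with_suffix(".npz")) as data:
        model.set_state([data[k] for k in data.files])
    return model
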