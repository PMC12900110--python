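"""Minimal layer-based neural-network core with explicit backpropagation.

Implements exactly the primitives the two decoder architectures need —
1-D convolution, batch normalization, max pooling, dropout, linear maps,
squeeze-and-excitation, CBAM-style spatial attention and residual blocks —
as numpy modules with hand-written forward/backward passes, plus an AdamW
optimizer with decoupled weight decay.

Conventions
-----------
* Feature maps are ``(N, C, T)`` arrays: batch, channels, positions.
* ``Module.forward`` caches whatever ``Module.backward`` needs; a backward
  call must follow the forward call it refers to.
* Weight init is fan-in-scaled uniform ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))``
  for weights and biases; batch-norm starts at unit scale / zero shift.
* All randomness (init, dropout, batch order) flows through one
  ``numpy.random.Generator`` supplied by the caller.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "ReLU",
    "Dropout",
    "Linear",
    "GlobalAvgPool1d",
    "Sequential",
    "SqueezeExcitation",
    "SpatialAttention",
    "ResidualBlock",
    "softmax",
    "cross_entropy",
    "AdamW",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: explicit registration of parameters and submodules."""

    def __init__(self):
        self._params: list[Param] = []
        self._mods: list[Module] = []
        self.training = True

    def register(self, p: Param) -> Param:
        self._params.append(p)
        return p

    def add(self, m: "Module") -> "Module":
        self._mods.append(m)
        return m

    def parameters(self) -> list[Param]:
        ps = list(self._params)
        for m in self._mods:
            ps.extend(m.parameters())
        return ps

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        bs: list[np.ndarray] = []
        for m in self._mods:
            bs.extend(m.buffers())
        return bs

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._mods:
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()] + self.buffers()

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model expects {len(arrays)}"
            )
        for dst, src in zip(arrays, state):
            if dst.shape != src.shape:
                raise ValueError(f"shape mismatch {dst.shape} vs {src.shape}")
            dst[...] = src

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv1d(Module):
    """1-D convolution (cross-correlation), 'same' padding unless stride > 1.

    With ``stride > 1`` the padding is still ``k // 2`` on both sides, so the
    output length is ``floor((T + 2*(k//2) - k) / stride) + 1``.
    """

    def __init__(self, cin: int, cout: int, k: int, *, stride: int = 1,
                 bias: bool = True, rng: np.random.Generator):
        super().__init__()
        if k % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        fan_in = cin * k
        self.weight = self.register(Param(_uniform_init(rng, (cout, cin, k), fan_in)))
        self.bias = self.register(Param(_uniform_init(rng, (cout,), fan_in))) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {x.shape[1]}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        win = win[:, :, :: self.stride]          # (N, Cin, L, K)
        n, _, l, _ = win.shape
        # im2col: one BLAS matmul instead of a tensor contraction
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * l, self.cin * self.k)
        self._cols, self._xshape, self._l = cols, x.shape, l
        y = cols @ self.weight.data.reshape(self.cout, -1).T   # (N*L, Cout)
        y = y.reshape(n, l, self.cout).transpose(0, 2, 1)
        if self.bias is not None:
            y = y + self.bias.data[None, :, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, t = self._xshape
        l = self._l
        dyt = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(n * l, self.cout)
        self.weight.grad += (dyt.T @ self._cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dyt.sum(axis=0)
        dcols = dyt @ self.weight.data.reshape(self.cout, -1)  # (N*L, Cin*K)
        dwin = dcols.reshape(n, l, self.cin, self.k)
        dxp = np.zeros((n, self.cin, t + 2 * self.pad))
        for kk in range(self.k):
            dxp[:, :, kk: kk + self.stride * l: self.stride] += \
                dwin[:, :, :, kk].transpose(0, 2, 1)
        return dxp[:, :, self.pad: self.pad + t]


class BatchNorm1d(Module):
    """Per-channel batch normalization over batch and position axes."""

    def __init__(self, c: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = self.register(Param(np.ones(c)))
        self.beta = self.register(Param(np.zeros(c)))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            n_eff = x.shape[0] * x.shape[2]
            self.running_mean *= 1 - self.momentum
            self.running_mean += self.momentum * mu
            unbiased = var * n_eff / max(n_eff - 1, 1)
            self.running_var *= 1 - self.momentum
            self.running_var += self.momentum * unbiased
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv_std[None, :, None]
        self._xhat, self._inv_std = xhat, inv_std
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.data[None, :, None]
        if not self.training:
            return dy * g * inv_std[None, :, None]
        n_eff = dy.shape[0] * dy.shape[2]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / n_eff) * (n_eff * dxhat - s1 - xhat * s2)


class MaxPool1d(Module):
    """Non-overlapping max pooling (kernel = stride), ragged tail dropped."""

    def __init__(self, stride: int):
        super().__init__()
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        s = self.stride
        n, c, t = x.shape
        l = t // s
        xr = x[:, :, : l * s].reshape(n, c, l, s)
        self._idx = xr.argmax(axis=3)
        self._tshape = (n, c, t)
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self.stride
        n, c, t = self._tshape
        l = dy.shape[2]
        dxr = np.zeros((n, c, l, s))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        dx = np.zeros((n, c, t))
        dx[:, :, : l * s] = dxr.reshape(n, c, l * s)
        return dx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear(Module):
    def __init__(self, fin: int, fout: int, *, bias: bool = True,
                 rng: np.random.Generator):
        super().__init__()
        self.fin, self.fout = fin, fout
        self.weight = self.register(Param(_uniform_init(rng, (fout, fin), fin)))
        self.bias = self.register(Param(_uniform_init(rng, (fout,), fin))) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.data.T
        if self.bias is not None:
            y += self.bias.data
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class GlobalAvgPool1d(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._t, axis=2) / self._t


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        for m in mods:
            self.add(m)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self._mods:
            x = m.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self._mods):
            dy = m.backward(dy)
        return dy


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SqueezeExcitation(Module):
    """Channel attention: global-average squeeze, bottleneck excitation,
    sigmoid-gated per-channel recalibration.

    ``z_c = mean_t u_c(t)``; ``s = sigmoid(W2 relu(W1 z))``; ``out_c = s_c u_c``.
    """

    def __init__(self, c: int, *, r: int = 16, bias: bool = False,
                 rng: np.random.Generator):
        super().__init__()
        if c % r != 0:
            raise ValueError(f"reduction ratio {r} must divide channel count {c}")
        self.c, self.r = c, r
        h = c // r
        self.w1 = self.register(Param(_uniform_init(rng, (h, c), c)))
        self.b1 = self.register(Param(_uniform_init(rng, (h,), c))) if bias else None
        self.w2 = self.register(Param(_uniform_init(rng, (c, h), h)))
        self.b2 = self.register(Param(_uniform_init(rng, (c,), h))) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x.mean(axis=2)                      # (N, C)
        a1 = z @ self.w1.data.T
        if self.b1 is not None:
            a1 += self.b1.data
        h1 = np.maximum(a1, 0.0)
        a2 = h1 @ self.w2.data.T
        if self.b2 is not None:
            a2 += self.b2.data
        s = _sigmoid(a2)                        # (N, C)
        self._cache = (x, z, a1, h1, s)
        return x * s[:, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, z, a1, h1, s = self._cache
        ds = (dy * x).sum(axis=2)
        dx = dy * s[:, :, None]
        da2 = ds * s * (1.0 - s)
        self.w2.grad += da2.T @ h1
        if self.b2 is not None:
            self.b2.grad += da2.sum(axis=0)
        dh1 = da2 @ self.w2.data
        da1 = dh1 * (a1 > 0)
        self.w1.grad += da1.T @ z
        if self.b1 is not None:
            self.b1.grad += da1.sum(axis=0)
        dz = da1 @ self.w1.data
        dx += dz[:, :, None] / x.shape[2]
        return dx

    @property
    def gate(self) -> np.ndarray:
        """Sigmoid gates from the most recent forward pass, shape (N, C)."""
        return self._cache[4]


class SpatialAttention(Module):
    """CBAM-style position attention: channel-wise mean and max are stacked,
    convolved (kernel 7, 'same' padding), squashed through a sigmoid, and the
    resulting per-position mask rescales every channel."""

    def __init__(self, *, k: int = 7, bias: bool = False,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = self.add(Conv1d(2, 1, k, bias=bias, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        avg = x.mean(axis=1, keepdims=True)     # (N, 1, T)
        mx_idx = x.argmax(axis=1)               # (N, T)
        mx = np.take_along_axis(x, mx_idx[:, None, :], axis=1)
        stacked = np.concatenate([avg, mx], axis=1)
        pre = self.conv.forward(stacked)        # (N, 1, T)
        a = _sigmoid(pre)
        self._cache = (x, mx_idx, a)
        return x * a

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mx_idx, a = self._cache
        da = (dy * x).sum(axis=1, keepdims=True)
        dx = dy * a
        dpre = da * a * (1.0 - a)
        dstacked = self.conv.backward(dpre)     # (N, 2, T)
        dx += dstacked[:, 0:1, :] / x.shape[1]
        dmax = np.zeros_like(x)
        np.put_along_axis(dmax, mx_idx[:, None, :], dstacked[:, 1:2, :], axis=1)
        return dx + dmax

    @property
    def mask(self) -> np.ndarray:
        """Attention mask from the most recent forward pass, shape (N, 1, T)."""
        return self._cache[2]


class ResidualBlock(Module):
    """conv-BN-ReLU-conv-BN with squeeze-and-excitation on the residual path,
    added to an identity (or 1x1-conv projected) shortcut, then ReLU.

    Convolutions on the residual path carry no bias (batch-norm follows).
    """

    def __init__(self, cin: int, cout: int, *, k: int = 3, r: int = 16,
                 use_se: bool = True, rng: np.random.Generator):
        super().__init__()
        self.conv1 = self.add(Conv1d(cin, cout, k, bias=False, rng=rng))
        self.bn1 = self.add(BatchNorm1d(cout))
        self.relu1 = self.add(ReLU())
        self.conv2 = self.add(Conv1d(cout, cout, k, bias=False, rng=rng))
        self.bn2 = self.add(BatchNorm1d(cout))
        self.se = self.add(SqueezeExcitation(cout, r=r, rng=rng)) if use_se else None
        if cin != cout:
            self.proj = self.add(Conv1d(cin, cout, 1, bias=False, rng=rng))
            self.proj_bn = self.add(BatchNorm1d(cout))
        else:
            self.proj = self.proj_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        f = self.relu1(self.bn1(self.conv1(x)))
        f = self.bn2(self.conv2(f))
        if self.se is not None:
            f = self.se(f)
        sc = x if self.proj is None else self.proj_bn(self.proj(x))
        y = f + sc
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        df = dy
        if self.se is not None:
            df = self.se.backward(df)
        df = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(df)))))
        if self.proj is None:
            return df + dy
        return df + self.proj.backward(self.proj_bn.backward(dy))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns ``(loss, dlogits)``."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params: list[Param], *, lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
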