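"""Minimal NumPy neural-network layers with explicit backpropagation.

The grading network needs only a handful of primitives — 2-D convolution,
batch normalisation, ReLU, global average pooling, a linear head, softmax
cross-entropy and Adam — so they are implemented directly on NumPy arrays
in NCHW layout (float32).  Everything is deterministic given the seed: no
threading-dependent reductions, no hidden entropy.

Convolutions are evaluated through strided sliding-window views plus a
single ``einsum``; the input gradient is accumulated kernel-tap by
kernel-tap, which for 3x3/1x1 kernels is both simple and fast at the image
sizes this package trains on.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "softmax",
    "cross_entropy",
    "Adam",
]

DTYPE = np.float32


class Layer:
    """Base class: trainable arrays live in ``params``, gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        self.params["w"] = _he_init(rng, (out_ch, in_ch, kernel, kernel), in_ch * kernel * kernel)
        self.params["b"] = np.zeros(out_ch, dtype=DTYPE)
        self._win: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def out_side(self, side: int) -> int:
        return (side + 2 * self.padding - self.kernel) // self.stride + 1

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        win = win[:, :, ::self.stride, ::self.stride]
        out = np.einsum("nchwij,ocij->nohw", win, self.params["w"], optimize=True)
        out += self.params["b"][None, :, None, None]
        if training:
            self._win = win
            self._xshape = x.shape
        return out.astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._win is not None and self._xshape is not None
        w = self.params["w"]
        self.grads["w"] = np.einsum("nohw,nchwij->ocij", dout, self._win, optimize=True).astype(DTYPE)
        self.grads["b"] = dout.sum(axis=(0, 2, 3)).astype(DTYPE)
        n, c, h, wd = self._xshape
        p, s, k = self.padding, self.stride, self.kernel
        ho, wo = dout.shape[2], dout.shape[3]
        dxp = np.zeros((n, c, h + 2 * p, wd + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("nohw,oc->nchw", dout, w[:, :, i, j], optimize=True)
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += contrib
        self._win = None
        return dxp[:, :, p:p + h, p:p + wd] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation; applied before the activation."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch, dtype=DTYPE)
        self.params["beta"] = np.zeros(ch, dtype=DTYPE)
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None]).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, inv_std = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = np.einsum("nchw,nchw->c", dout, xhat).astype(DTYPE)
        self.grads["beta"] = dout.sum(axis=(0, 2, 3)).astype(DTYPE)
        g = self.params["gamma"][None, :, None, None]
        dxhat = dout * g
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - sum_d / m - xhat * sum_dx / m) * inv_std[None, :, None, None]
        self._cache = None
        return dx.astype(DTYPE, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mask = x > 0
        if training:
            self._mask = mask
        return np.where(mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """Collapse each feature map to its spatial mean: (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)).astype(DTYPE)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = _he_init(rng, (in_f, out_f), in_f)
        self.params["b"] = np.zeros(out_f, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = (self._x.T @ dout).astype(DTYPE)
        self.grads["b"] = dout.sum(axis=0).astype(DTYPE)
        return dout @ self.params["w"].T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)


class Adam:
    """Adam with the standard bias-corrected first/second moment estimates."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = self.m[li][k] / bc1
                vhat = self.v[li][k] / bc2
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
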