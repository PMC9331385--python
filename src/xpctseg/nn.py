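"""Minimal CPU neural-network engine for 2D dense segmentation.

Implements exactly the pieces a U-Net needs — 3x3 "same" convolution via
im2col + BLAS matmul, ReLU, 2x2 max pooling, nearest-neighbour 2x
upsampling, channel concatenation, a 1x1 output convolution, softmax
cross-entropy and an RMSProp optimizer — with explicit forward/backward
passes in float32. Single-sample (batch 1) semantics throughout: feature
maps are (channels, H, W).

All randomness is injected through a ``numpy.random.Generator``; there is
no global RNG state, so identical seeds give bit-identical weights and
training trajectories on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Parameter:
    """A learnable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (shape preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * c_in))  # He init for ReLU nets
        self.w = Parameter(rng.normal(0.0, std, size=(9 * c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self._col = None
        self._shape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xp = np.zeros((c, h + 2, w + 2), dtype=F32)
        xp[:, 1:-1, 1:-1] = x
        win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (c,h,w,3,3)
        col = win.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)
        col = np.ascontiguousarray(col)
        y = col @ self.w.data + self.b.data
        self._col, self._shape = col, (c, h, w)
        return y.reshape(h, w, self.c_out).transpose(2, 0, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dyf = np.ascontiguousarray(dy.transpose(1, 2, 0).reshape(h * w, self.c_out))
        self.w.grad += self._col.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcol = (dyf @ self.w.data.T).reshape(h, w, c, 3, 3)
        dxp = np.zeros((c, h + 2, w + 2), dtype=F32)
        for i in range(3):
            for j in range(3):
                dxp[:, i:i + h, j:j + w] += dcol[:, :, :, i, j].transpose(2, 0, 1)
        self._col = None
        return dxp[:, 1:-1, 1:-1]


class Conv1x1:
    """Per-pixel linear map across channels (the output head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / c_in)
        self.w = Parameter(rng.normal(0.0, std, size=(c_in, c_out)))
        self.b = Parameter(np.zeros(c_out))
        self.c_in, self.c_out = c_in, c_out
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xf = np.ascontiguousarray(x.reshape(c, h * w).T)
        self._x, self._shape = xf, (c, h, w)
        y = xf @ self.w.data + self.b.data
        return y.T.reshape(self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dyf = np.ascontiguousarray(dy.reshape(self.c_out, h * w).T)
        self.w.grad += self._x.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dx = (dyf @ self.w.data.T).T.reshape(c, h, w)
        self._x = None
        return dx


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; input H, W must be even. Ties route the gradient
    to the first maximal element (fixed argmax order ⇒ deterministic)."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
        xr = xr.reshape(c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = (c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dxr = np.zeros((c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        return dx.reshape(c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        return dy.reshape(c, h, 2, w, 2).sum(axis=(2, 4))


class DoubleConv:
    """conv3x3 → ReLU → conv3x3 → ReLU, the standard U-Net block."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv3x3(c_in, c_out, rng)
        self.r1 = ReLU()
        self.c2 = Conv3x3(c_out, c_out, rng)
        self.r2 = ReLU()

    def params(self):
        return self.c1.params() + self.c2.params()

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the leading (class) axis of (K, H, W) scores."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=F32)
    return e / e.sum(axis=0, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Mean per-pixel categorical cross-entropy.

    Returns (loss, dlogits, probs); ``target`` holds integer class ids of
    shape (H, W).
    """
    k = logits.shape[0]
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=F32)
    s = e.sum(axis=0, keepdims=True)
    probs = e / s
    logp = z - np.log(s)
    picked = np.take_along_axis(logp, target[None], axis=0)[0]
    loss = float(-picked.mean())
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, target[None], 1.0, axis=0)
    dlogits = (probs - onehot) / F32(target.size)
    return loss, dlogits, probs


class RMSProp:
    """RMSProp with L2 weight decay and optional heavy-ball momentum.

    ``rho`` is the exponential smoothing constant of the squared-gradient
    accumulator; ``momentum`` (if > 0) adds a torch-style velocity buffer
    on the preconditioned step.
    """

    def __init__(self, params: list[Parameter], lr: float, rho: float = 0.9,
                 momentum: float = 0.0, weight_decay: float = 0.0,
                 eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.rho = F32(rho)
        self.momentum = F32(momentum)
        self.weight_decay = F32(weight_decay)
        self.eps = F32(eps)
        self._sq = [np.zeros_like(p.data) for p in params]
        self._buf = [np.zeros_like(p.data) for p in params] if momentum > 0 else None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay > 0:
                g = g + self.weight_decay * p.data
            sq = self._sq[i]
            sq *= self.rho
            sq += (1 - self.rho) * g * g
            update = g / (np.sqrt(sq) + self.eps)
            if self._buf is not None:
                buf = self._buf[i]
                buf *= self.momentum
                buf += update
                update = buf
            p.data -= F32(self.lr) * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0
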