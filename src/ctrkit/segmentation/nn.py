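"""Minimal numpy neural-network primitives: conv/pool/upsample layers,
softmax cross-entropy + soft-Dice loss, and Adam.

Tensors are NCHW float64.  Each layer caches what its backward pass needs;
`backward` must be called with the same batch that was last forwarded.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    """Stride-1 'same' convolution; kernel 1, 2, or 3.

    Even kernels pad on the bottom/right only, so output spatial dims always
    equal input dims.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel not in (1, 2, 3):
            raise ValueError("kernel must be 1, 2, or 3")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        k = kernel
        self._pad = ((k - 1) // 2, k // 2)  # (before, after) on each spatial axis

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p0, p1 = self._pad
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
        # (N, C, H, W, k, k) -> (N, H, W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        cols = self._im2col(x).reshape(n * h * w, -1)
        self._cache = (cols, x.shape)
        out = cols @ self.w.T + self.b
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        k = self.kernel
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_ch)
        self.dw += dflat.T @ cols
        self.db += dflat.sum(axis=0)
        dcols = (dflat @ self.w).reshape(n, h, w, c, k, k)
        p0, p1 = self._pad
        dxp = np.zeros((n, c, h + p0 + p1, w + p0 + p1))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p0 : p0 + h, p0 : p0 + w]

    def params(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": self.b}

    def grads(self) -> dict[str, np.ndarray]:
        return {"w": self.dw, "b": self.db}

    def n_params(self) -> int:
        return self.w.size + self.b.size


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; requires even spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x2 pooling")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class UpsampleNearest2(Layer):
    """Nearest-neighbour x2 up-sampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(logits: np.ndarray) -> np.ndarray:
    """Channel-axis softmax for NCHW logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def ce_dice_loss(
    logits: np.ndarray, labels: np.ndarray, dice_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Per-pixel cross-entropy plus (1 - mean soft Dice); returns (loss, dlogits).

    ``labels`` is an integer class map of shape (N, H, W).
    """
    n, k, h, w = logits.shape
    p = softmax(logits)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)

    npix = n * h * w
    ce = -np.log(np.take_along_axis(p, labels[:, None], axis=1) + 1e-12).sum() / npix
    dlogits = (p - onehot) / npix

    eps = 1.0
    axes = (0, 2, 3)
    inter = (p * onehot).sum(axis=axes)
    denom = p.sum(axis=axes) + onehot.sum(axis=axes)
    dice = (2 * inter + eps) / (denom + eps)
    dice_loss = 1.0 - dice.mean()
    if dice_weight:
        # dL/dp_c = -(1/K) * (2*t*(denom+eps) - (2*inter+eps)) / (denom+eps)^2
        num = 2 * onehot * (denom + eps)[None, :, None, None] - (2 * inter + eps)[
            None, :, None, None
        ]
        g = -(num / (denom + eps)[None, :, None, None] ** 2) / k
        # softmax jacobian: dlogit = p * (g - sum_j p_j g_j)
        dlogits = dlogits + dice_weight * p * (g - (p * g).sum(axis=1, keepdims=True))
    return float(ce + dice_weight * dice_loss), dlogits


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, p in self.params.items():
            g = grads[key]
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1**self.t)
            vhat = self.v[key] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
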