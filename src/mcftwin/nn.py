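"""Minimal CNN building blocks (numpy, float32) for the reconstruction cascade.

Implements exactly what the cascade needs: 3x3 same-convolutions via
im2col/col2im-as-convolution, leaky rectifier / sigmoid, 2x average-pool down / nearest
up-sampling, channel concat, residual add, and Adam.  All randomness flows
through an explicit numpy Generator so builds and training runs are
reproducible bit-for-bit on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3x3", "LeakyReLU", "Sigmoid", "BoundedLinear01",
           "AvgPool2", "UpsampleNearest2", "Adam"]

F32 = np.float32


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*9) patches of the 1-padded input."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (B, C, H, W, 3, 3) -> (B, H, W, C, 3, 3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
    return np.ascontiguousarray(cols, dtype=F32)


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 scale: float | None = None):
        fan_in = in_ch * 9
        std = scale if scale is not None else np.sqrt(2.0 / fan_in)
        self.w = rng.normal(0.0, std, size=(out_ch, fan_in)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x)
        if train:
            self._cols, self._shape = cols, x.shape
        y = cols @ self.w.T + self.b
        return y.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, co, h, w = gy.shape
        g2 = np.ascontiguousarray(gy.transpose(0, 2, 3, 1).reshape(-1, co), dtype=F32)
        self.dw += g2.T @ self._cols
        self.db += g2.sum(axis=0)
        # input gradient = same-convolution of gy with the rotated, transposed kernel
        wk = self.w.reshape(co, self.in_ch, 3, 3)
        wrot = wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.in_ch, co * 9)
        cols_g = _im2col(gy)
        gx = cols_g @ wrot.T
        self._cols = None
        return gx.reshape(b, h, w, self.in_ch).transpose(0, 3, 1, 2)


class LeakyReLU:
    """Leaky rectifier (slope 0.1 for negative inputs).

    The small negative slope prevents units from dying irrecoverably, which
    a narrow cascade cannot afford: with hard rectification some seeds
    collapse to a constant predictor within the first epoch.
    """

    SLOPE = F32(0.1)

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.SLOPE * x)

    def backward(self, gy):
        return gy * np.where(self._mask, F32(1.0), self.SLOPE)

    def params(self):
        return []


class Sigmoid:
    def forward(self, x, train=True):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y.astype(F32)

    def backward(self, gy):
        return gy * self._y * (1.0 - self._y)

    def params(self):
        return []


class BoundedLinear01:
    """[0, 1]-bounding output activation: identity inside the range, small
    leaky slope outside (so saturated pixels keep a restoring gradient)."""

    LEAK = F32(0.05)  # straight-through leak: output is an exact clip

    def forward(self, x, train=True):
        self._inside = (x > 0) & (x < 1)
        return np.clip(x, 0.0, 1.0).astype(F32)

    def backward(self, gy):
        return gy * np.where(self._inside, F32(1.0), self.LEAK)

    def params(self):
        return []


class AvgPool2:
    def forward(self, x, train=True):
        b, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, gy):
        g = np.repeat(np.repeat(gy, 2, axis=2), 2, axis=3) / 4.0
        return g.astype(F32)

    def params(self):
        return []


class UpsampleNearest2:
    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, gy):
        b, c, h, w = gy.shape
        return gy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(F32)

    def params(self):
        return []


class Adam:
    """Adam optimizer over (param, grad) array pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
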