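"""Minimal NumPy neural-network layers with manual gradients.

Provides exactly what the segmentation U-Net and the recurrent classifier
need: 3x3/1x1 convolutions (im2col), ReLU, 2x2 max-pool, nearest-neighbour
upsampling, and an Adam optimizer.  Everything is float64 and deterministic
given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2", "Upsample2", "Adam", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Conv2d:
    """k x k same-padded convolution over NCHW batches (k odd)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.b = np.zeros(c_out)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, pad = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = np.empty((n, c, k * k, h, w))
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            cols[:, :, idx] = xp[:, :, di:di + h, dj:dj + w]
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        Wm = self.W.reshape(self.W.shape[0], -1)
        y = np.matmul(Wm[None], cols) + self.b[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        k, pad = self.k, self.k // 2
        dyf = dy.reshape(n, -1, h * w)
        Wm = self.W.reshape(self.W.shape[0], -1)
        self.dW += np.einsum("nfp,ncp->fc", dyf, cols).reshape(self.W.shape)
        self.db += dyf.sum(axis=(0, 2))
        dcols = np.matmul(Wm.T[None], dyf).reshape(n, c, k * k, h, w)
        dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
        for idx in range(k * k):
            di, dj = divmod(idx, k)
            dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, idx]
        return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class ReLU:
    def __init__(self):
        self._mask = None
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2 (even spatial dims required)."""

    def __init__(self):
        self._argmax = None
        self._shape = None
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = xr.argmax(axis=-1)
        self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._argmax[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x spatial upsampling."""

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Adam:
    """Adam over (param, grad) pairs updated in place."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
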