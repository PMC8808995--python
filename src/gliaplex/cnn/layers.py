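"""Minimal CPU neural-network layers with explicit backprop.

Only what the profile-image classifier needs: 3×3 same-padding convolution
(im2col), ReLU, 2×2 max pooling, dropout, dense layers, and the Adam / SGD
/ RMSprop update rules. Arrays are NCHW float64; every layer caches what
its backward pass needs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Flatten",
    "Dense",
    "make_optimizer",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n, c, h, w, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    d = dcols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(Layer):
    """3×3 convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        self.k, self.pad = k, k // 2
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k, self.pad)
        n, _, h, w = x.shape
        out = self._cols @ self.W + self.b  # (n, h*w, c_out)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, c_out, h, w = dy.shape
        dflat = dy.transpose(0, 2, 3, 1).reshape(n, h * w, c_out)
        self.dW[...] = np.tensordot(self._cols, dflat, axes=([0, 1], [0, 1]))
        self.db[...] = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W.T
        return _col2im(dcols, self._x_shape, self.k, self.pad)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2 (ties share the gradient)."""

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xr = x[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        self._mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        self._x_shape = x.shape
        return out

    def backward(self, dy):
        n, c, h, w = self._x_shape
        ho, wo = h // 2, w // 2
        dxr = self._mask * dy[:, :, :, None, :, None]
        dx = np.zeros(self._x_shape)
        dx[:, :, : ho * 2, : wo * 2] = dxr.reshape(n, c, ho * 2, wo * 2)
        return dx


class Dropout(Layer):
    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._x_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._x_shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class _Optimizer:
    def __init__(self, params, grads, lr, weight_decay=0.0):
        self.params, self.grads = params, grads
        self.lr, self.wd = lr, weight_decay

    def _effective_grads(self):
        # decoupled-from-loss L2: add wd * param to each gradient
        return [g + self.wd * p for p, g in zip(self.params, self.grads)]


class SGD(_Optimizer):
    def __init__(self, params, grads, lr, weight_decay=0.0, momentum=0.9):
        super().__init__(params, grads, lr, weight_decay)
        self.m = [np.zeros_like(p) for p in params]
        self.momentum = momentum

    def step(self):
        for p, g, m in zip(self.params, self._effective_grads(), self.m):
            m *= self.momentum
            m += g
            p -= self.lr * m


class Adam(_Optimizer):
    def __init__(self, params, grads, lr, weight_decay=0.0, betas=(0.9, 0.999), eps=1e-8):
        super().__init__(params, grads, lr, weight_decay)
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.b1, self.b2, self.eps, self.t = betas[0], betas[1], eps, 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self._effective_grads(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, params, grads, lr, weight_decay=0.0, alpha=0.99, eps=1e-8):
        super().__init__(params, grads, lr, weight_decay)
        self.v = [np.zeros_like(p) for p in params]
        self.alpha, self.eps = alpha, eps

    def step(self):
        for p, g, v in zip(self.params, self._effective_grads(), self.v):
            v *= self.alpha
            v += (1 - self.alpha) * g**2
            p -= self.lr * g / (np.sqrt(v) + self.eps)


def make_optimizer(name: str, params, grads, lr: float, weight_decay: float = 0.0):
    table = {"adam": Adam, "sgd": SGD, "rmsprop": RMSprop}
    if name not in table:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(table)}")
    return table[name](params, grads, lr, weight_decay)
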