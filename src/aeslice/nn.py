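"""A small CPU neural-network engine on numpy arrays.

Implements exactly the pieces the slice autoencoder needs — 2D convolution
("same" padding), batch normalization, ELU, sigmoid, 2x2 average pooling,
2x nearest-neighbour upsampling, mean-squared-error loss and the Adam
optimizer — with hand-derived backward passes. Layout is NCHW throughout.

Convolutions are computed as nine shift-and-matmul accumulations (one per
kernel tap), which keeps memory low and routes the work through BLAS.
Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np


@dataclass
class Param:
    """A trainable array with its gradient accumulator."""

    name: str
    data: np.ndarray
    grad: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    train_mode: bool = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> List[Param]:
        return []

    def state_arrays(self) -> List[np.ndarray]:
        """Non-trainable persistent arrays (e.g. BN moving statistics)."""
        return []


class Conv2d(Layer):
    """k x k convolution with 'same' zero padding, stride 1."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None,
                 dtype=np.float32):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.cin, self.cout, self.k = cin, cout, k
        rng = rng or np.random.default_rng(0)
        # He-style variance scaling on fan-in (conv weights), zero biases
        std = np.sqrt(2.0 / (cin * k * k))
        w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(dtype)
        self.W = Param("W", w)
        self.b = Param("b", np.zeros(cout, dtype=dtype))
        self._xp: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp = xp
        acc = np.zeros((self.cout, B, H, Wd), dtype=x.dtype)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, :, i:i + H, j:j + Wd]
                acc += np.tensordot(self.W.data[:, :, i, j], xs, axes=([1], [1]))
        y = acc.transpose(1, 0, 2, 3)
        y += self.b.data[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        B, O, H, Wd = dy.shape
        p = self.k // 2
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for i in range(self.k):
            for j in range(self.k):
                xs = xp[:, :, i:i + H, j:j + Wd]
                self.W.grad[:, :, i, j] += np.tensordot(
                    dy, xs, axes=([0, 2, 3], [0, 2, 3]))
                dcx = np.tensordot(self.W.data[:, :, i, j], dy, axes=([0], [1]))
                dxp[:, :, i:i + H, j:j + Wd] += dcx.transpose(1, 0, 2, 3)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def params(self):
        return [self.W, self.b]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with moving statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param("gamma", np.ones(c, dtype=dtype))
        self.beta = Param("beta", np.zeros(c, dtype=dtype))
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mu).astype(
                self.running_mean.dtype)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(
                self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.data[None, :, None, None] * xhat \
            + self.beta.data[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        if not self.train_mode:
            return dxhat * inv_std[None, :, None, None]
        B, C, H, W = dy.shape
        m = B * H * W
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.running_mean, self.running_var]


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._y = None

    def forward(self, x):
        y = x.copy()
        neg = x <= 0
        y[neg] = self.alpha * np.expm1(x[neg])
        self._y = y
        return y

    def backward(self, dy):
        y = self._y
        return dy * np.where(y > 0, 1.0, y + self.alpha).astype(dy.dtype)


class Sigmoid(Layer):
    def forward(self, x):
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class AvgPool2(Layer):
    """2x2 average pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even, got {H}x{W}")
        self._shape = x.shape
        return x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(self, dy):
        B, C, H, W = self._shape
        return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25


class NearestUpsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x):
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, dy):
        for lyr in reversed(self.layers):
            dy = lyr.backward(dy)
        return dy

    def params(self):
        return [p for lyr in self.layers for p in lyr.params()]

    def state_arrays(self):
        return [a for lyr in self.layers for a in lyr.state_arrays()]

    def set_train(self, mode: bool):
        for lyr in self.layers:
            lyr.train_mode = mode
            if isinstance(lyr, Sequential):
                lyr.set_train(mode)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
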