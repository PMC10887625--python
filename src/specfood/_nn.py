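"""Minimal NumPy CNN engine used by the conversion and analysis networks.

Layers operate on float32 arrays in NCHW layout.  Convolutions are
realised as im2col + BLAS matmul, and their input gradient as a second
convolution with spatially flipped kernels, so both passes stay inside
dense matrix products.  Training is plain mini-batch stochastic gradient
descent, ``W <- W - lr * dE/dW`` (optional classical momentum behind a
flag), which keeps the optimisation an exact implementation of the
update rule the models are defined with.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "Dense", "ReLU", "Sigmoid", "MaxPool2", "Upsample2",
    "Flatten", "SGD", "mse_loss", "softmax", "softmax_xent_loss", "mape_loss",
]


class Layer:
    """Base layer: forward/backward plus parameter access."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padded convolution with bias, He-initialised."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        self.W = (rng.standard_normal((cout, cin, k, k)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (N, C, H, W) -> (N*H*W, C*k*k)
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        n, c, h, w = x.shape
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * self.k * self.k
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} channels, got {c}")
        cols = self._im2col(x)
        self._cols, self._shape = cols, x.shape
        out = cols @ self.W.reshape(self.cout, -1).T + self.b
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, _, h, w = self._shape
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.dW[...] = (g2.T @ self._cols).reshape(self.W.shape)
        self.db[...] = g2.sum(axis=0)
        # dx = same-padded correlation of g with flipped kernels, cin<->cout.
        p = self.k // 2
        gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(gp, (self.k, self.k), axis=(2, 3))
        gcols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, self.cout * self.k * self.k
        )
        Wb = self.W[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(
            self.cout * self.k * self.k, self.cin
        )
        dx = (gcols @ Wb).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        self._cols = None
        return np.ascontiguousarray(dx)


class Dense(Layer):
    def __init__(self, din: int, dout: int, rng: np.random.Generator,
                 scale: float | None = None) -> None:
        s = np.sqrt(2.0 / din) if scale is None else scale
        self.W = (rng.standard_normal((din, dout)) * s).astype(np.float32)
        self.b = np.zeros(dout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        out = g @ self.W.T
        self._x = None
        return out


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        # clip pre-activations: sigmoid saturates, float32 exp overflows
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        return self._y

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(out.reshape(n, c, h, w))


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = g.shape
        return g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class SGD:
    """Plain stochastic gradient descent, optional classical momentum."""

    def __init__(self, layers: Sequence[Layer], lr: float,
                 momentum: float = 0.0) -> None:
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.layers = list(layers)
        self.lr = lr
        self.momentum = momentum
        self._vel = None
        if momentum > 0:
            self._vel = [np.zeros_like(p) for l in self.layers
                         for p in l.params()]

    def step(self) -> None:
        i = 0
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                if self._vel is not None:
                    self._vel[i] = self.momentum * self._vel[i] - self.lr * g
                    p += self._vel[i]
                else:
                    p -= self.lr * g
                i += 1


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Per-pixel mean squared error and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(np.float32)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_loss(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(np.float32)


def mape_loss(
    pred: np.ndarray, target: np.ndarray, eps: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Mean absolute percentage error (fractional) and gradient w.r.t. pred.

    ``target`` must be positive (the 5 kcal floor is applied upstream);
    ``eps`` guards the denominator.
    """
    denom = target + eps
    n = pred.size
    loss = float(np.mean(np.abs(pred - target) / denom))
    grad = np.sign(pred - target) / denom / n
    return loss, grad.astype(np.float32)
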