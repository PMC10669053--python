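"""Layers with explicit forward/backward passes.

Internal tensor layout is channels-last (N, H, W, C), float32 — each
3×3 convolution then reduces to nine shifted (N·H·W, C) × (C, O)
matrix products over memory-contiguous row chunks, which is where
NumPy/BLAS is fastest.  Each layer caches what its backward pass needs
during forward; ``backward(dy)`` returns the gradient w.r.t. the layer
input and accumulates parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k×k convolution, stride 1, symmetric zero padding (same size).

    Weight shape is (k*k, C_in, C_out): one (C_in, C_out) projection
    per kernel offset.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = k // 2
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Param(rng.normal(0.0, std, size=(k * k, cin, cout)))
        self.bias = Param(np.zeros(cout))
        self._col = None

    def params(self):
        return [self.weight, self.bias]

    def _offsets(self):
        k = self.k
        return [(t // k, t % k) for t in range(k * k)]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        k, p = self.k, self.pad
        if p:
            xp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
            xp[:, p : p + h, p : p + w, :] = x
        else:
            xp = np.ascontiguousarray(x, dtype=np.float32)
        # im2col buffer (k*k, N*H*W, C): kept for the backward pass so
        # the shifted windows are materialized only once
        col = np.empty((k * k, n * h * w, c), dtype=np.float32)
        y = np.empty((n * h * w, self.cout), dtype=np.float32)
        y[:] = self.bias.value
        for t, (ki, kj) in enumerate(self._offsets()):
            col[t] = xp[:, ki : ki + h, kj : kj + w, :].reshape(n * h * w, c)
            y += col[t] @ self.weight.value[t]
        if train:
            self._col = col
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy):
        col = self._col
        self._col = None
        n, h, w, _ = dy.shape
        k, p, c = self.k, self.pad, self.cin
        dy_mat = dy.reshape(n * h * w, self.cout)
        self.bias.grad += dy_mat.sum(axis=0)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=np.float32)
        for t, (ki, kj) in enumerate(self._offsets()):
            self.weight.grad[t] += col[t].T @ dy_mat
            dxp[:, ki : ki + h, kj : kj + w, :] += (dy_mat @ self.weight.value[t].T).reshape(
                n, h, w, c
            )
        return dxp[:, p : p + h, p : p + w, :] if p else dxp


class ConvTranspose2x2(Layer):
    """2×2 stride-2 transposed convolution (learned ×2 upsampling).

    Weight shape (4, C_in, C_out): one projection per output sub-pixel.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / cin)
        self.weight = Param(rng.normal(0.0, std, size=(4, cin, cout)))
        self.bias = Param(np.zeros(cout))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        xm = x.reshape(n * h * w, c)
        y = np.empty((n, h, w, 2, 2, self.cout), dtype=np.float32)
        for t in range(4):
            y[:, :, :, t // 2, t % 2, :] = (xm @ self.weight.value[t] + self.bias.value / 4.0).reshape(
                n, h, w, self.cout
            )
        if train:
            self._x = xm
        # (n, h, 2, w, 2, c) ordering for the spatial interleave
        return np.ascontiguousarray(y.transpose(0, 1, 3, 2, 4, 5)).reshape(
            n, 2 * h, 2 * w, self.cout
        )

    def backward(self, dy):
        xm = self._x
        self._x = None
        n, h2, w2, o = dy.shape
        h, w = h2 // 2, w2 // 2
        dyb = dy.reshape(n, h, 2, w, 2, o).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros_like(xm)
        for t in range(4):
            d = np.ascontiguousarray(dyb[:, :, :, t // 2, t % 2, :]).reshape(n * h * w, o)
            self.weight.grad[t] += xm.T @ d
            self.bias.grad += d.sum(axis=0) / 4.0
            dx += d @ self.weight.value[t].T
        return dx.reshape(n, h, w, self.cin)


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            # one reduction pass: E[x] and E[x^2]
            mu = x.mean(axis=(0, 1, 2), dtype=np.float32)
            var = np.maximum((x * x).mean(axis=(0, 1, 2), dtype=np.float32) - mu * mu, 0.0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = (x - mu) * inv_std
        y = self.gamma.value * xhat + self.beta.value
        if train:
            self._cache = (xhat, inv_std)
        return y

    def backward(self, dy):
        xhat, inv_std = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        dx = (dxhat - sum_dxhat / m - xhat * (sum_dxhat_xhat / m)) * inv_std
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """2×2 max pooling, stride 2 (spatial dims must be even).

    Works on the four strided quadrant views; ties route the gradient
    to the first matching quadrant in row-major window order.
    """

    _OFFSETS = ((0, 0), (0, 1), (1, 0), (1, 1))

    def __init__(self):
        self._x = None
        self._y = None

    def forward(self, x, train=False):
        y = x[:, ::2, ::2, :].copy()
        for a, b in self._OFFSETS[1:]:
            np.maximum(y, x[:, a::2, b::2, :], out=y)
        if train:
            self._x = x
            self._y = y
        return y

    def backward(self, dy):
        x, y = self._x, self._y
        self._x = self._y = None
        dx = np.zeros_like(x)
        taken = np.zeros(dy.shape, dtype=bool)
        for a, b in self._OFFSETS:
            hit = (x[:, a::2, b::2, :] == y) & ~taken
            dx[:, a::2, b::2, :] = dy * hit
            taken |= hit
        return dx


class UpsampleNearest2(Layer):
    """Nearest-neighbour ×2 upsampling."""

    def forward(self, x, train=False):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy):
        n, h2, w2, c = dy.shape
        return dy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(
            np.float32
        ) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        dx = dy * self._mask
        self._mask = None
        return dx


class ChannelSoftmax(Layer):
    """Softmax over the channel (last) axis; sums to 1 per pixel."""

    def __init__(self):
        self._p = None

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        if train:
            self._p = p
        return p

    def backward(self, dy):
        p = self._p
        self._p = None
        return (p * (dy - (p * dy).sum(axis=-1, keepdims=True))).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
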