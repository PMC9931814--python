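"""Minimal NumPy layers with explicit forward/backward passes.

Tensors are laid out as (batch, D, H, W, C). Convolutions are computed as a
sum over the 27 kernel taps of shifted tensordots, which keeps peak memory
at one (B, D, H, W, C) buffer instead of a full im2col matrix.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    def params(self):  # [(name, array, grad-array)]
        return []

    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


def xavier_init(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Conv3d(Layer):
    """3D convolution, kernel k^3, stride 1, zero padding (k-1)/2."""

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd")
        rng = rng or np.random.default_rng(0)
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan = kernel ** 3
        self.w = xavier_init(rng, (kernel, kernel, kernel, c_in, c_out),
                             fan * c_in, fan * c_out)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x_pad = None

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def n_params(self) -> int:
        return self.w.size + self.b.size

    def _taps(self):
        k = self.k
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    yield i, j, l

    def forward(self, x, training=False):
        k, p = self.k, (self.k - 1) // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
        B, D, H, W, _ = x.shape
        y = np.empty((B, D, H, W, self.c_out), dtype=DTYPE)
        y[:] = self.b
        for i, j, l in self._taps():
            xs = xp[:, i:i + D, j:j + H, l:l + W, :]
            y += np.tensordot(xs, self.w[i, j, l], axes=([4], [0]))
        if training:
            self._x_pad = xp
        return y

    def backward(self, dy):
        k, p = self.k, (self.k - 1) // 2
        xp = self._x_pad
        B, Dp, Hp, Wp, _ = xp.shape
        D, H, W = Dp - 2 * p, Hp - 2 * p, Wp - 2 * p
        dxp = np.zeros_like(xp)
        self.db[:] = dy.sum(axis=(0, 1, 2, 3))
        for i, j, l in self._taps():
            xs = xp[:, i:i + D, j:j + H, l:l + W, :]
            self.dw[i, j, l] = np.tensordot(xs, dy, axes=([0, 1, 2, 3], [0, 1, 2, 3]))
            dxp[:, i:i + D, j:j + H, l:l + W, :] += np.tensordot(
                dy, self.w[i, j, l], axes=([4], [1]))
        self._x_pad = None
        if p:
            return dxp[:, p:-p, p:-p, p:-p, :]
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalization over (B, D, H, W)."""

    def __init__(self, c, eps=1e-5, momentum=0.9):
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def forward(self, x, training=False):
        axes = (0, 1, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if training:
            self._cache = (xhat, inv_std.astype(DTYPE), x.shape)
        return (self.gamma * xhat + self.beta).astype(DTYPE)

    def backward(self, dy):
        xhat, inv_std, shape = self._cache
        n = np.prod([shape[i] for i in range(4)])
        axes = (0, 1, 2, 3)
        self.dgamma[:] = (dy * xhat).sum(axis=axes)
        self.dbeta[:] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        dx = (inv_std / n) * (n * dxhat - dxhat.sum(axis=axes)
                              - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x, training=False):
        B, D, H, W, C = x.shape
        xr = x.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C)
        flat = xr.transpose(0, 1, 3, 5, 7, 2, 4, 6).reshape(
            B, D // 2, H // 2, W // 2, C, 8)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if training:
            self._arg, self._in_shape = arg, x.shape
        return np.ascontiguousarray(y)

    def backward(self, dy):
        B, D, H, W, C = self._in_shape
        flat = np.zeros((B, D // 2, H // 2, W // 2, C, 8), dtype=dy.dtype)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        x = flat.reshape(B, D // 2, H // 2, W // 2, C, 2, 2, 2).transpose(
            0, 1, 5, 2, 6, 3, 7, 4).reshape(B, D, H, W, C)
        self._arg = None
        return np.ascontiguousarray(x)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x, training=False):
        y = x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)
        return y

    def backward(self, dy):
        B, D, H, W, C = dy.shape
        return dy.reshape(B, D // 2, 2, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4, 6))


class Sigmoid(Layer):
    def forward(self, x, training=False):
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if training:
            self._y = y
        return y.astype(DTYPE)

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx.astype(DTYPE)
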