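"""Minimal CPU neural-network engine used by the segmentation module.

Implements exactly the layer set the multi-decoder 2D network needs —
3x3 same-padding convolutions, 2x2 max pooling, 2x2 stride-2 transposed
convolutions, batch normalization, ReLU/sigmoid — with manual
backpropagation and an Adam optimizer.  Arrays are NCHW float32; the
forward/backward of every layer is verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "MaxPool2D",
    "BatchNorm2D",
    "ReLU",
    "Sigmoid",
    "Adam",
    "Sequential",
]

DTYPE = np.float32


class Layer:
    def params(self):
        """List of (param_array, grad_array) pairs; updated in place."""
        return []

    def forward(self, x, training=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """kxk convolution, stride 1, 'same' zero padding (k odd), via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None):
        if k % 2 != 1:
            raise ValueError("Conv2D expects an odd kernel size")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = np.random.default_rng() if rng is None else rng
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._xshape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=True):
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        self._xshape = x.shape
        if k == 1:
            cols = x.transpose(0, 2, 3, 1).reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
            # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * h * w, c * k * k
            )
        self._cols = cols if training else None
        y = cols @ self.W.reshape(self.c_out, -1).T
        y += self.b
        return y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n, _, h, w = dy.shape
        k, p, c = self.k, self.k // 2, self.c_in
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW[...] = (dyf.T @ self._cols).reshape(self.W.shape)
        self.db[...] = dyf.sum(axis=0)
        dcols = dyf @ self.W.reshape(self.c_out, -1)
        if k == 1:
            return dcols.reshape(n, h, w, c).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + h, kj : kj + w] += dcols[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w]


class ConvTranspose2D(Layer):
    """2x2 transposed convolution with stride 2 (non-overlapping upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng=None):
        self.c_in, self.c_out = c_in, c_out
        rng = np.random.default_rng() if rng is None else rng
        self.W = (rng.standard_normal((c_in, c_out, 2, 2)) * np.sqrt(2.0 / c_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, training=True):
        n, c, h, w = x.shape
        self._x = x if training else None
        # (n,c,h,w) x (c,o,2,2) -> (n,h,w,o,2,2)
        t = np.tensordot(x, self.W, axes=([1], [0]))
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.c_out, 2 * h, 2 * w)
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        n, o, H, W = dy.shape
        h, w = H // 2, W // 2
        dt = dy.reshape(n, o, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (n,h,w,o,2,2)
        dx = np.tensordot(dt, self.W, axes=([3, 4, 5], [1, 2, 3])).transpose(0, 3, 1, 2)
        self.dW[...] = np.tensordot(self._x, dt, axes=([0, 2, 3], [0, 1, 2]))
        self.db[...] = dy.sum(axis=(0, 2, 3))
        return np.ascontiguousarray(dx)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; ties resolved to the first maximum."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x, training=True):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2D needs even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy):
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class BatchNorm2D(Layer):
    """Per-channel batch normalization (momentum 0.9, epsilon 1e-3)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-3):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def forward(self, x, training=True):
        if training:
            m = x.shape[0] * x.shape[2] * x.shape[3]
            mean = np.einsum("nchw->c", x) / m
            # biased variance via E[x^2] - mean^2 in one fused reduction
            var = np.einsum("nchw,nchw->c", x, x) / m - mean * mean
            var = np.maximum(var, 0.0)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean.astype(x.dtype)[None, :, None, None]) * inv[None, :, None, None]
        if training:
            self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy):
        xhat, inv, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.dgamma[...] = np.einsum("nchw,nchw->c", dy, xhat)
        self.dbeta[...] = np.einsum("nchw->c", dy)
        dxhat = dy * self.gamma[None, :, None, None]
        mu1 = (np.einsum("nchw->c", dxhat) / m).astype(dy.dtype)
        mu2 = (np.einsum("nchw,nchw->c", dxhat, xhat) / m).astype(dy.dtype)
        dx = (
            dxhat - mu1[None, :, None, None] - xhat * mu2[None, :, None, None]
        ) * inv[None, :, None, None]
        return dx


class ReLU(Layer):
    def forward(self, x, training=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x, training=True):
        # numerically stable logistic
        self._y = np.where(
            x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))), np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))
        )
        return self._y

    def backward(self, dy):
        return dy * self._y * (1.0 - self._y)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for lay in self.layers:
            out.extend(lay.params())
        return out

    def forward(self, x, training=True):
        for lay in self.layers:
            x = lay.forward(x, training)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Adam:
    """Adam optimizer with framework-default hyperparameters."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
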