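"""Minimal 1-D neural-network layers with reverse-mode gradients.

The segmentation network used by this package is small (≈80k parameters),
so its layers — 1-D convolution, transposed convolution, batch
normalization, max-pooling, dropout, leaky-ReLU — are implemented directly
on numpy arrays with hand-written backward passes and an Adam optimizer.
All activations use the layout ``(batch, length, channels)``; arrays are
float32, which keeps training bitwise-reproducible on one machine while
halving memory traffic.

Convolution padding is 'same' (left pad ``(k-1)//2``); transposed
convolutions use stride ``s`` and crop ``(k-s)//2`` leading samples so the
output length is exactly ``s`` times the input length.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


DTYPE = np.float32


def xavier_uniform(rng, k, cin, cout):
    """Glorot/Xavier uniform initialization for a (k, cin, cout) kernel."""
    limit = np.sqrt(6.0 / (k * cin + k * cout))
    return rng.uniform(-limit, limit, size=(k, cin, cout)).astype(DTYPE)


class Layer:
    """Base class: parameterized layers hold ``params`` and ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def n_trainable(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1D(Layer):
    def __init__(self, cin, cout, k, rng):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.pad_left = (k - 1) // 2
        self.pad_right = k - 1 - self.pad_left
        self.params = {"W": xavier_uniform(rng, k, cin, cout),
                       "b": np.zeros(cout, dtype=DTYPE)}

    def forward(self, x, training=False):
        k = self.k
        x = np.ascontiguousarray(x, dtype=DTYPE)
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # (N, L, k, C) columns, flattened to match W.reshape(k*cin, cout)
        cols = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
        n, L = x.shape[0], x.shape[1]
        self._cols = np.ascontiguousarray(cols).reshape(n * L, k * self.cin)
        self._nL = (n, L)
        W2 = self.params["W"].reshape(k * self.cin, self.cout)
        y = self._cols @ W2 + self.params["b"]
        return y.reshape(n, L, self.cout)

    def backward(self, dy):
        n, L, _ = dy.shape
        k, cin = self.k, self.cin
        dy2 = np.ascontiguousarray(dy, dtype=DTYPE).reshape(n * L, self.cout)
        W2 = self.params["W"].reshape(k * cin, self.cout)
        self.grads["W"] = (self._cols.T @ dy2).reshape(k, cin, self.cout)
        self.grads["b"] = dy2.sum(axis=0)
        dcols = (dy2 @ W2.T).reshape(n, L, k, cin)
        dxp = np.zeros((n, L + k - 1, cin), dtype=DTYPE)
        for j in range(k):
            dxp[:, j: j + L] += dcols[:, :, j]
        return dxp[:, self.pad_left: self.pad_left + L]


class ConvTranspose1D(Layer):
    """Stride-``s`` transposed convolution; output length = s * input length."""

    def __init__(self, cin, cout, k, rng, stride=2):
        super().__init__()
        if k < stride:
            raise ValueError("kernel must be >= stride")
        self.cin, self.cout, self.k, self.s = cin, cout, k, stride
        self.off = (k - stride) // 2
        self.params = {"W": xavier_uniform(rng, k, cin, cout),
                       "b": np.zeros(cout, dtype=DTYPE)}

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, L, _ = x.shape
        k, s, off = self.k, self.s, self.off
        self._x2 = x.reshape(n * L, self.cin)
        self._nL = (n, L)
        full = np.zeros((n, (L - 1) * s + k, self.cout), dtype=DTYPE)
        W = self.params["W"]
        for j in range(k):
            full[:, j: j + s * L: s] += (self._x2 @ W[j]).reshape(
                n, L, self.cout)
        return full[:, off: off + s * L] + self.params["b"]

    def backward(self, dy):
        n, L = self._nL
        k, s, off = self.k, self.s, self.off
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        dfull = np.zeros((n, (L - 1) * s + k, self.cout), dtype=DTYPE)
        dfull[:, off: off + s * L] = dy
        W = self.params["W"]
        dx2 = np.zeros((n * L, self.cin), dtype=DTYPE)
        dW = np.zeros_like(W)
        for j in range(k):
            sl = np.ascontiguousarray(dfull[:, j: j + s * L: s]).reshape(
                n * L, self.cout)
            dx2 += sl @ W[j].T
            dW[j] = self._x2.T @ sl
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dx2.reshape(n, L, self.cin)


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, c, momentum=0.99, eps=1e-3):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, dtype=DTYPE),
                       "beta": np.zeros(c, dtype=DTYPE)}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=DTYPE)
        if training:
            mean = x.mean(axis=(0, 1), dtype=np.float64).astype(DTYPE)
            var = x.var(axis=(0, 1), dtype=np.float64).astype(DTYPE)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._m = x.shape[0] * x.shape[1]
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        xhat, std, m = self._xhat, self._std, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        if not self._training:
            return dy * g / std
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=(0, 1))
                - xhat * (dxhat * xhat).mean(axis=(0, 1))) / std


class MaxPool1D(Layer):
    def __init__(self, factor=2):
        super().__init__()
        self.f = factor

    def forward(self, x, training=False):
        n, L, c = x.shape
        f = self.f
        xr = x.reshape(n, L // f, f, c)
        self._arg = xr.argmax(axis=2)
        self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        n, Lp, c = dy.shape
        f = self.f
        dxr = np.zeros((n, Lp, f, c), dtype=DTYPE)
        np.put_along_axis(dxr, self._arg[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        return dxr.reshape(self._shape)


class LeakyReLU(Layer):
    def __init__(self, alpha=0.25):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, dy):
        return np.where(self._neg, self.alpha * dy, dy)


class Dropout(Layer):
    def __init__(self, rate, rng):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.rate)
                      / (1 - self.rate)).astype(DTYPE)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z, y):
    """Mean binary cross-entropy of sigmoid(z) against y, and its gradient
    in z. Stable for large |z|."""
    z = np.asarray(z, dtype=DTYPE)
    y = np.asarray(y, dtype=DTYPE)
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))),
                   dtype=np.float64)
    grad = ((sigmoid(z) - y) / z.size).astype(DTYPE)
    return float(loss), grad


class Adam:
    """Adam optimizer over a list of parameterized layers."""

    def __init__(self, layers, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for key, p in layer.params.items():
                g = layer.grads[key]
                m[key] = self.b1 * m[key] + (1 - self.b1) * g
                v[key] = self.b2 * v[key] + (1 - self.b2) * g * g
                p -= self.lr * (m[key] / b1t) / (np.sqrt(v[key] / b2t) + self.eps)
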