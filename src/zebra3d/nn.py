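"""Minimal numpy neural-network engine.

Implements exactly the pieces the keypoint-regression network needs:
im2col-based 2-D convolution, batch normalization, leaky rectifier,
dense layers, global average pooling, residual composition, and Adam.
Layers expose ``forward(x, train)`` / ``backward(dy)`` and collect their
parameters and gradients for the optimizer; everything is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "BatchNorm2d", "BatchNorm1d", "LeakyReLU", "Dense",
    "GlobalAvgPool", "ScaledSigmoid", "Sequential", "Residual", "Adam",
]

F32 = np.float32


class Layer:
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs."""
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, C, H, W) -> column matrix (N, C*k*k, OH*OW)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (x.shape[2] - k) // stride + 1
    ow = (x.shape[3] - k) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]          # (N, C, OH, OW, k, k)
    cols = view.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    for ki in range(k):
        for kj in range(k):
            dx[:, :, ki:ki + oh * stride:stride, kj:kj + ow * stride:stride] \
                += dcols[:, :, ki, kj]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(cout, cin * k * k)).astype(F32)
        self.b = np.zeros(cout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, pad
        self.cin, self.cout = cin, cout

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self.x_shape = x.shape
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        self.cols = cols
        y = np.einsum("oc,ncp->nop", self.W, cols) + self.b[None, :, None]
        return y.reshape(x.shape[0], self.cout, oh, ow)

    def backward(self, dy):
        n, _, oh, ow = dy.shape
        dyf = dy.reshape(n, self.cout, oh * ow)
        self.dW[...] = np.einsum("nop,ncp->oc", dyf, self.cols)
        self.db[...] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", self.W, dyf)
        return _col2im(dcols, self.x_shape, self.k, self.stride, self.pad)


class _BatchNorm(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    axes: tuple = ()

    def _shape(self, v):
        raise NotImplementedError

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mean).astype(F32)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        self.istd = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - self._shape(mean)) * self._shape(self.istd)
        self.m = x.size // x.shape[1]
        return self._shape(self.gamma) * self.xhat + self._shape(self.beta)

    def backward(self, dy):
        self.dgamma[...] = (dy * self.xhat).sum(axis=self.axes)
        self.dbeta[...] = dy.sum(axis=self.axes)
        g = self._shape(self.gamma * self.istd)
        dxhat = dy * self._shape(self.gamma)
        mean_dxhat = self._shape(dxhat.mean(axis=self.axes))
        mean_dxhat_x = self._shape((dxhat * self.xhat).mean(axis=self.axes))
        return self._shape(self.istd) * (dxhat - mean_dxhat
                                         - self.xhat * mean_dxhat_x)


class BatchNorm2d(_BatchNorm):
    axes = (0, 2, 3)

    def _shape(self, v):
        return v[None, :, None, None]


class BatchNorm1d(_BatchNorm):
    axes = (0,)

    def _shape(self, v):
        return v[None, :]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=True):
        self.neg = x < 0
        return np.where(self.neg, self.slope * x, x)

    def backward(self, dy):
        return np.where(self.neg, self.slope * dy, dy)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0, np.sqrt(2.0 / nin), size=(nin, nout)).astype(F32)
        self.b = np.zeros(nout, dtype=F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=True):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self.x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self.in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self.in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w),
                               self.in_shape).copy()


class ScaledSigmoid(Layer):
    """sigmoid(x) * scale — bounds keypoint outputs to [0, scale]."""

    def __init__(self, scale: float = 141.0):
        self.scale = scale

    def forward(self, x, train=True):
        self.s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self.scale * self.s

    def backward(self, dy):
        return dy * self.scale * self.s * (1.0 - self.s)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Residual(Layer):
    """y = branch(x) + shortcut(x)."""

    def __init__(self, branch: Layer, shortcut: Layer):
        self.branch = branch
        self.shortcut = shortcut

    def params(self):
        return self.branch.params() + self.shortcut.params()

    def forward(self, x, train=True):
        return self.branch.forward(x, train) + self.shortcut.forward(x, train)

    def backward(self, dy):
        return self.branch.backward(dy) + self.shortcut.backward(dy)


class Adam:
    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
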