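"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the residual classifier needs: 2-D convolution (im2col),
batch normalization, ReLU, 3x3/2 max pooling, global average pooling and a
dense head. Activations are cached on the forward pass only when
``train=True`` so inference stays memory-light. All parameters are float32
and initialization is a pure function of the RNG handed in.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "relu",
    "softmax",
    "categorical_crossentropy",
    "binary_form_crossentropy",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
]

_EPS_CLIP = 1e-7


def relu(x):
    """Elementwise max(x, 0); works on scalars and arrays."""
    return np.maximum(x, 0)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``.

    Shift-invariant by construction: the running maximum is subtracted
    before exponentiation.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("softmax of an empty vector is undefined")
    if not np.all(np.isfinite(x)):
        raise ValueError("softmax input must be finite")
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def categorical_crossentropy(y: np.ndarray, a: np.ndarray) -> float:
    """Mean multiclass cross-entropy ``-1/n * sum_i sum_k y_ik ln a_ik``.

    ``y`` holds one-hot targets, ``a`` predicted probabilities; both may be
    single vectors or (n, k) batches. Probabilities are clipped away from 0.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if y.shape != a.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs predictions {a.shape}")
    a = np.clip(a, _EPS_CLIP, 1.0)
    return float(-(y * np.log(a)).sum(axis=1).mean())


def binary_form_crossentropy(y: np.ndarray, a: np.ndarray) -> float:
    """Two-term (Bernoulli-sum) cross-entropy, summed over components.

    ``-1/n * sum_i sum_k [y ln a + (1 - y) ln(1 - a)]`` — the printed form of
    the loss; training itself uses :func:`categorical_crossentropy`.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if y.shape != a.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs predictions {a.shape}")
    a = np.clip(a, _EPS_CLIP, 1.0 - _EPS_CLIP)
    terms = y * np.log(a) + (1.0 - y) * np.log(1.0 - a)
    return float(-terms.sum(axis=1).mean())


class Layer:
    """Base class: forward/backward plus named parameter access."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, param, grad) triples; grads are allocated lazily."""
        return []


class Conv2d(Layer):
    """k x k convolution via im2col. Input layout (N, C, H, W)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))  # He initialization
        self.W = rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        s, k = self.stride, self.k
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        win = win[:, :, :ho, :wo]
        # (N, C, Ho, Wo, k, k) -> (N*Ho*Wo, C*k*k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, self.cin * k * k)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        cols = self._im2col(xp, ho, wo).astype(np.float32, copy=False)
        y = cols @ self.W.reshape(self.cout, -1).T + self.b
        if train:
            self._cache = (cols, xp.shape, (n, ho, wo))
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, ho, wo) = self._cache
        s, k, p = self.stride, self.k, self.pad
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout).astype(np.float32, copy=False)
        self.dW[...] = (g.T @ cols).reshape(self.W.shape)
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.reshape(self.cout, -1)).reshape(n, ho, wo, self.cin, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp

    def parameters(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * istd[None, :, None, None]
        if train:
            self._cache = (xhat, istd)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, istd = self._cache
        axes = (0, 2, 3)
        nt = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * xhat).sum(axis=axes)
        self.dbeta[...] = grad.sum(axis=axes)
        g = self.gamma[None, :, None, None] * istd[None, :, None, None]
        dx = g * (grad
                  - self.dbeta[None, :, None, None] / nt
                  - xhat * self.dgamma[None, :, None, None] / nt)
        self._cache = None
        return dx.astype(np.float32, copy=False)

    def parameters(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def state(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """k x k max pooling with stride s; padding uses -inf."""

    def __init__(self, k: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.stride, self.pad = k, stride, pad

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p, s, k = self.pad, self.stride, self.k
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        n, c, h, w = xp.shape
        ho = (h - k) // s + 1
        wo = (w - k) // s + 1
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s][:, :, :ho, :wo]
        out = win.max(axis=(4, 5))
        if train:
            self._cache = (win, out, xp.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        win, out, xp_shape = self._cache
        p, s, k = self.pad, self.stride, self.k
        n, c, ho, wo = grad.shape
        dxp = np.zeros(xp_shape, dtype=np.float32)
        assigned = np.zeros(out.shape, dtype=bool)
        for i in range(k):
            for j in range(k):
                hit = (win[:, :, :, :, i, j] == out) & ~assigned
                assigned |= hit
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += grad * hit
        self._cache = None
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool(Layer):
    """Spatial mean over (H, W): (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(grad[:, :, None, None] / (h * w), (n, c, h, w)).astype(np.float32)


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, scale, size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        self._x = None
        return (grad @ self.W.T).astype(np.float32, copy=False)

    def parameters(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", p, g) for n, p, g in layer.parameters())
        return out
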