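"""Minimal 1-D convolutional network engine (numpy).

Implements exactly the layer types the sleep-wake architecture needs —
(f, k, s) 1-D convolutions with ReLU, dense layers, 50% dropout and a
2-class softmax output — together with reverse-mode gradients and the Adam
optimizer. Everything is float64 and driven by explicit
``numpy.random.Generator`` streams, so a training run is a pure function of
(data, config, seed).

Networks are built in :mod:`cardiosleep.model`; this module only knows about
layers, sequential containers and optimization.
"""

from __future__ import annotations

import numpy as np

from .errors import ArchitectureError


class Layer:
    trainable = True

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []


class Conv1D(Layer):
    """Valid-mode strided 1-D convolution: (N, C, L) -> (N, F, L_out)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        if kernel < 1 or stride < 1 or filters < 1:
            raise ArchitectureError("conv parameters must be positive")
        self.c, self.f, self.k, self.s = in_channels, filters, kernel, stride
        scale = np.sqrt(2.0 / (in_channels * kernel))  # He initialization
        self.W = rng.normal(0.0, scale, size=(filters, in_channels, kernel))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def out_len(self, L: int) -> int:
        n = (L - self.k) // self.s + 1
        if n < 1:
            raise ArchitectureError(f"conv output length {n} for input length {L}")
        return n

    def _col_index(self, L: int) -> np.ndarray:
        starts = np.arange(self.out_len(L)) * self.s
        return starts[None, :] + np.arange(self.k)[:, None]  # (k, L_out)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        idx = self._col_index(x.shape[-1])
        cols = x[:, :, idx]  # (N, C, k, L_out)
        out = np.einsum("fck,nckl->nfl", self.W, cols) + self.b[:, None]
        self._cache = (x.shape, idx, cols)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, idx, cols = self._cache
        self.dW = np.einsum("nfl,nckl->fck", grad, cols)
        self.db = grad.sum(axis=(0, 2))
        dcols = np.einsum("fck,nfl->nckl", self.W, grad)
        dx = np.zeros(x_shape)
        np.add.at(dx, (slice(None), slice(None), idx), dcols)
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        if n_in < 1 or n_out < 1:
            raise ArchitectureError("dense layer sizes must be positive")
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ArchitectureError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
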