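"""Minimal feed-forward / 1-D convolutional network engine in numpy.

The regressors used here are tiny (a few thousand parameters), so the
package carries its own dense/conv layers, backprop and Adam rather than
depending on a deep-learning framework.  Shapes follow the Keras "channels
last" convention: dense inputs are (batch, features), conv inputs are
(batch, length, channels) with 'valid' padding.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

__all__ = ["Dense", "Conv1D", "ReLU", "Sigmoid", "Flatten", "Sequential", "Adam"]


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = _glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Conv1D(Layer):
    """'valid' 1-D convolution, kernel k, (batch, length, channels) layout."""

    def __init__(self, kernel: int, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.w = _glorot_uniform(rng, (kernel, c_in, c_out), fan_in, fan_out)
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # im2col: one matmul instead of per-tap products
        b, l, c = x.shape
        l_out = l - self.kernel + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        cols = cols.transpose(0, 1, 3, 2).reshape(b * l_out, self.kernel * c)
        self._shape = (b, l, c, l_out)
        self._cols = cols
        y = cols @ self.w.reshape(self.kernel * c, -1) + self.b
        return y.reshape(b, l_out, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, l, c, l_out = self._shape
        dy_flat = dy.reshape(b * l_out, -1)
        self.grads[0][...] = (self._cols.T @ dy_flat).reshape(self.w.shape)
        self.grads[1][...] = dy_flat.sum(axis=0)
        dcols = (dy_flat @ self.w.reshape(self.kernel * c, -1).T).reshape(
            b, l_out, self.kernel, c
        )
        dx = np.zeros((b, l, c))
        for j in range(self.kernel):
            dx[:, j : j + l_out, :] += dcols[:, :, j, :]
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Sequential:
    def __init__(self, layers: List[Layer], input_shape: tuple):
        self.layers = layers
        self.input_shape = input_shape  # per-sample shape, e.g. (28,) or (28, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == len(self.input_shape):
            x = x[None, ...]
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of per-sample shape {self.input_shape}, got {x.shape[1:]}"
            )
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params)

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: List[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    """Adam with bias correction; the learning rate is passed per step."""

    def __init__(self, params: List[np.ndarray], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    """Plain stochastic gradient descent (switchable alternative to Adam)."""

    def __init__(self, params: List[np.ndarray]):
        self.params = params

    def step(self, grads: List[np.ndarray], lr: float) -> None:
        for p, g in zip(self.params, grads):
            p -= lr * g
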