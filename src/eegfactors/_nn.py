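"""Minimal NumPy neural-network plumbing: initializers and first-order
optimizers (SGD with momentum, Adam, RMSprop) operating on dicts of named
parameter arrays.  Everything is seeded and bit-reproducible."""

from __future__ import annotations

import numpy as np


def glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Optimizer:
    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        raise NotImplementedError


class SGDMomentum(Optimizer):
    def __init__(self, lr: float = 0.01, momentum: float = 0.5):
        self.lr, self.momentum = lr, momentum
        self._v: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            v = self._v.get(k)
            v = self.momentum * v + g if v is not None else g.copy()
            self._v[k] = v
            params[k] -= self.lr * v


class Adam(Optimizer):
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params, grads):
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            m = self._m.setdefault(k, np.zeros_like(g))
            v = self._v.setdefault(k, np.zeros_like(g))
            m[:] = b1 * m + (1 - b1) * g
            v[:] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self._t)
            vhat = v / (1 - b2**self._t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.lr, self.rho, self.eps = lr, rho, eps
        self._s: dict[str, np.ndarray] = {}

    def step(self, params, grads):
        for k, g in grads.items():
            s = self._s.setdefault(k, np.zeros_like(g))
            s[:] = self.rho * s + (1 - self.rho) * g * g
            params[k] -= self.lr * g / (np.sqrt(s) + self.eps)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


ACTIVATIONS = {
    "linear": (lambda x: x, lambda x, y: np.ones_like(y)),
    "tanh": (np.tanh, lambda x, y: 1.0 - y * y),
    "sigmoid": (sigmoid, lambda x, y: y * (1.0 - y)),
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(x.dtype)),
}


def activation_pair(tag: str):
    """Return (f, df) where df takes (pre-activation, post-activation)."""
    try:
        return ACTIVATIONS[tag]
    except KeyError:
        raise ValueError(f"unknown activation tag {tag!r}") from None


def minibatches(n: int, batch: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for start in range(0, n, batch):
        yield idx[start:start + batch]
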