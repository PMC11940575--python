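"""Minimal dense-network core: layers, activations, Adam.

The networks in this package are small multilayer perceptrons (the SDF
decoder and the stage-2 CVAE), so forward and backward passes are written
explicitly in numpy.  Everything is float64 and seeded, which makes
training runs bit-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np

_ACTS = ("relu", "tanh", "linear")


class Dense:
    """Affine layer ``y = x @ W + b`` with W of shape (fan_in, fan_out)."""

    def __init__(self, fan_in: int, fan_out: int, activation: str, rng: np.random.Generator):
        if activation not in _ACTS:
            raise ValueError(f"unknown activation {activation!r}")
        scale = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
        self.W = rng.normal(0.0, scale, size=(fan_in, fan_out))
        self.b = np.zeros(fan_out)
        self.activation = activation

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "tanh":
        return np.tanh(z)
    return z


def _act_grad(z: np.ndarray, y: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0.0).astype(float)
    if kind == "tanh":
        return 1.0 - y * y
    return np.ones_like(z)


class MLP:
    """A stack of :class:`Dense` layers with explicit backward pass."""

    def __init__(self, sizes: list[int], activations: list[str], rng: np.random.Generator):
        assert len(sizes) - 1 == len(activations)
        self.layers = [
            Dense(sizes[i], sizes[i + 1], activations[i], rng)
            for i in range(len(activations))
        ]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, want_cache: bool = False):
        cache = []
        for layer in self.layers:
            z = x @ layer.W + layer.b
            y = _act(z, layer.activation)
            if want_cache:
                cache.append((x, z, y))
            x = y
        return (x, cache) if want_cache else x

    def backward(self, cache, grad_out: np.ndarray):
        """Given d(loss)/d(output), return (d(loss)/d(input), grads).

        ``grads`` is a flat list aligned with :attr:`params`.
        """
        grads: list[np.ndarray] = []
        g = grad_out
        for layer, (x, z, y) in zip(reversed(self.layers), reversed(cache)):
            gz = g * _act_grad(z, y, layer.activation)
            grads.append(gz.sum(axis=0))       # db
            grads.append(x.T @ gz)             # dW
            g = gz @ layer.W.T
        grads.reverse()
        # reverse produced [... dW, db] per layer in forward order
        return g, grads


class Adam:
    """Adam over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class RowAdam:
    """Adam over rows of a 2-D table, for sparse per-shape code updates.

    Moment estimates and step counts are kept per row so that shapes
    appearing in different numbers of minibatches are each on their own
    Adam schedule.
    """

    def __init__(self, table: np.ndarray, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.table = table
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = np.zeros_like(table)
        self.v = np.zeros_like(table)
        self.t = np.zeros(len(table), dtype=np.int64)

    def step(self, rows: np.ndarray, grads: np.ndarray) -> None:
        b1, b2 = self.beta1, self.beta2
        self.t[rows] += 1
        t = self.t[rows][:, None].astype(float)
        self.m[rows] = b1 * self.m[rows] + (1 - b1) * grads
        self.v[rows] = b2 * self.v[rows] + (1 - b2) * grads * grads
        mhat = self.m[rows] / (1.0 - b1**t)
        vhat = self.v[rows] / (1.0 - b2**t)
        self.table[rows] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
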