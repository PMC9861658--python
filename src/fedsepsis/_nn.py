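"""Minimal dense-network machinery: an MLP with explicit backprop and Adam.

Kept deliberately small — just what the adversarial imputer and the sequence
model need.  Everything operates on plain float64 ndarrays so results are
bit-reproducible across runs given the same seed.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class MLP:
    """Fully connected net, ReLU hidden layers, sigmoid output, manual backprop."""

    def __init__(self, dims: list[int], rng: np.random.Generator):
        self.dims = list(dims)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / d_in)
            self.weights.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self._cache: list = []

    @property
    def params(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = [x]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = sigmoid(z) if i == last else relu(z)
            self._cache.append(h)
        return h

    def backward(self, dout: np.ndarray):
        """Given dL/d(output), return (param grads aligned with .params, dL/dx)."""
        acts = self._cache
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        last = len(self.weights) - 1
        delta = dout * acts[-1] * (1.0 - acts[-1])  # sigmoid'
        for i in range(last, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.weights[i].T) * (acts[i] > 0)
            else:
                delta = delta @ self.weights[i].T
        return [*grads_w, *grads_b], delta
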