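"""Minimal dense-layer primitives with explicit gradients.

Both embedding models in this package (the VAE and the GraphSAGE
network) are small MLPs trained on CPU, so layers, analytic backprop and
Adam are implemented directly on NumPy arrays. All parameters live in a
flat ``name -> ndarray`` dict, which keeps optimizer state, checkpointing
and seeding trivial and bit-reproducible.
"""

from __future__ import annotations

import numpy as np


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def dense_init(rng: np.random.Generator, d_in: int, d_out: int, name: str, params: dict) -> None:
    params[f"{name}.W"] = glorot(rng, d_in, d_out)
    params[f"{name}.b"] = np.zeros(d_out)


def dense_forward(x: np.ndarray, name: str, params: dict) -> np.ndarray:
    return x @ params[f"{name}.W"] + params[f"{name}.b"]


def dense_backward(x: np.ndarray, dy: np.ndarray, name: str, params: dict, grads: dict) -> np.ndarray:
    """Accumulate dW/db for layer `name` and return dx."""
    grads[f"{name}.W"] = grads.get(f"{name}.W", 0.0) + x.T @ dy
    grads[f"{name}.b"] = grads.get(f"{name}.b", 0.0) + dy.sum(axis=0)
    return dy @ params[f"{name}.W"].T


class Adam:
    """Adam optimizer over a flat parameter dict."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            g = np.asarray(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def sigmoid(x):
    # numerically stable logistic
    out = np.empty_like(x, dtype=float) if isinstance(x, np.ndarray) else None
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out = np.empty_like(x)
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.shape else float(out)
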