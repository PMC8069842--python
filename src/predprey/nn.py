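"""Minimal dense neural-network layer used by the policies and critics.

Implements a two-hidden-layer perceptron with tanh activations, exact
manual backpropagation, and a decoupled-weight-decay Adam optimizer.  The
networks here are small (an observation window in, nine action values out),
so plain vectorized numpy is fast enough for desk-scale training while
keeping every arithmetic step explicit and deterministic.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["MLP", "AdamW", "softmax", "log_softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis."""
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=-1, keepdims=True)


def log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=-1, keepdims=True))


class MLP:
    """Two-hidden-layer perceptron ``in -> h1 -> h2 -> out`` with tanh units.

    The final layer is initialized at a much smaller scale so that freshly
    created policy networks emit near-zero logits, i.e. start out acting
    (almost) uniformly at random.
    """

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 final_scale: float = 1e-3) -> None:
        if len(sizes) != 4:
            raise ValueError("MLP expects [input, hidden1, hidden2, output] sizes")
        self.sizes = tuple(int(s) for s in sizes)
        self.params: List[np.ndarray] = []
        for i, (fan_in, fan_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            scale = np.sqrt(1.0 / fan_in)
            if i == 2:
                scale *= final_scale
            self.params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))

    # -- forward ---------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Single-input forward pass (1-D input, 1-D output)."""
        W1, b1, W2, b2, W3, b3 = self.params
        h1 = np.tanh(x @ W1 + b1)
        h2 = np.tanh(h1 @ W2 + b2)
        return h2 @ W3 + b3

    def forward_batch(self, X: np.ndarray) -> Tuple[np.ndarray, tuple]:
        """Batched forward pass returning outputs and a backprop cache."""
        W1, b1, W2, b2, W3, b3 = self.params
        H1 = np.tanh(X @ W1 + b1)
        H2 = np.tanh(H1 @ W2 + b2)
        out = H2 @ W3 + b3
        return out, (X, H1, H2)

    # -- backward --------------------------------------------------------
    def backward(self, cache: tuple, grad_out: np.ndarray) -> List[np.ndarray]:
        """Gradients of ``sum(grad_out * output)`` w.r.t. every parameter."""
        X, H1, H2 = cache
        W1, b1, W2, b2, W3, b3 = self.params
        gW3 = H2.T @ grad_out
        gb3 = grad_out.sum(axis=0)
        d2 = (grad_out @ W3.T) * (1.0 - H2 * H2)
        gW2 = H1.T @ d2
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ W2.T) * (1.0 - H1 * H1)
        gW1 = X.T @ d1
        gb1 = d1.sum(axis=0)
        return [gW1, gb1, gW2, gb2, gW3, gb3]

    # -- parameter vector ------------------------------------------------
    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.params])

    def set_flat(self, flat: np.ndarray) -> None:
        offset = 0
        for i, p in enumerate(self.params):
            self.params[i] = flat[offset:offset + p.size].reshape(p.shape).copy()
            offset += p.size
        if offset != flat.size:
            raise ValueError("flat parameter vector has the wrong length")

    def copy(self) -> "MLP":
        clone = object.__new__(MLP)
        clone.sizes = self.sizes
        clone.params = [p.copy() for p in self.params]
        return clone


class AdamW(object):
    """Adam with decoupled weight decay, applied to a list of arrays."""

    def __init__(self, params: List[np.ndarray], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
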