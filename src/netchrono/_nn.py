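"""Minimal fully-connected networks with Adam, in numpy.

Two consumers: the comparative pairwise scorer (a shared trunk f mapping an
edge vector to a scalar, trained on the logistic pairwise loss) and the
autoencoder used for the SDNE-style embedding view.  Deliberately small:
full-batch gradients over minibatches, tanh hidden units, deterministic given
the seed.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


class MLP:
    """Feed-forward net with tanh hidden layers and a linear output."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / (fan_in + fan_out))
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.b.append(np.zeros(fan_out))
        # Adam state
        self._m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(v) for v in self.b]
        self._v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(v) for v in self.b]
        self._t = 0

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, List[np.ndarray]]:
        """Return output and per-layer activations (for backprop)."""
        acts = [x]
        h = x
        n_layers = len(self.W)
        for k, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if k < n_layers - 1:
                h = np.tanh(h)
            acts.append(h)
        return h, acts

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, acts: List[np.ndarray], grad_out: np.ndarray) -> Tuple[List[np.ndarray], List[np.ndarray]]:
        """Gradients of the summed loss w.r.t. weights and biases."""
        gW = [np.zeros_like(w) for w in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        g = grad_out
        for k in range(len(self.W) - 1, -1, -1):
            gW[k] = acts[k].T @ g
            gb[k] = g.sum(axis=0)
            if k > 0:
                g = (g @ self.W[k].T) * (1.0 - acts[k] ** 2)
        return gW, gb

    def adam_step(self, gW: List[np.ndarray], gb: List[np.ndarray],
                  lr: float = 1e-2, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._t += 1
        params = self.W + self.b
        grads = gW + gb
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mh = m / (1 - beta1 ** self._t)
            vh = v / (1 - beta2 ** self._t)
            p -= lr * mh / (np.sqrt(vh) + eps)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
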