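"""Minimal feedforward neural-network building blocks (numpy, manual backprop).

Just enough machinery for the reference codec and property head: dense
layers, ReLU/tanh, inverted dropout, softmax cross-entropy and Adam.
Deterministic given the seeds passed in.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "softmax_cross_entropy"]


class Dense:
    """Affine layer y = x W + b with cached input for backprop."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He-style init; fine for both relu and tanh at these widths
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class MLP:
    """Dense stack with a fixed activation on hidden layers, linear output.

    ``dropout`` (inverted, applied after each hidden activation) is active
    only when ``forward(..., training=True)`` is given an rng.
    """

    def __init__(
        self,
        sizes: list[int],
        activation: str = "relu",
        dropout: float = 0.0,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.layers = [Dense(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]
        self.activation = activation
        self.dropout = float(dropout)
        self.sizes = list(sizes)
        self._h: list[np.ndarray] = []
        self._masks: list[np.ndarray | None] = []

    def _act(self, z: np.ndarray) -> np.ndarray:
        return np.maximum(z, 0.0) if self.activation == "relu" else np.tanh(z)

    def _act_grad(self, h: np.ndarray) -> np.ndarray:
        return (h > 0).astype(float) if self.activation == "relu" else 1.0 - h**2

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        self._h = []
        self._masks = []
        h = x
        for layer in self.layers[:-1]:
            h = self._act(layer.forward(h))
            if training and self.dropout > 0.0:
                if rng is None:
                    raise ValueError("training-mode dropout needs an rng")
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
                self._masks.append(mask)
            else:
                self._masks.append(None)
            self._h.append(h)
        return self.layers[-1].forward(h)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        grad = self.layers[-1].backward(np.atleast_2d(grad_out))
        for layer, h, mask in zip(
            reversed(self.layers[:-1]), reversed(self._h), reversed(self._masks)
        ):
            if mask is not None:
                grad = grad * mask
            # relu': sign survives dropout scaling (masked units already have
            # zero grad); tanh' from the post-dropout cache is only exact for
            # dropout 0 — pair tanh with dropout 0 in this codebase
            grad = grad * self._act_grad(h)
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out += [l.W, l.b]
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out += [l.dW, l.db]
        return out

    def state(self) -> dict:
        return {f"l{i}.{n}": getattr(l, n) for i, l in enumerate(self.layers) for n in ("W", "b")}

    def load_state(self, state: dict) -> None:
        for i, l in enumerate(self.layers):
            l.W = np.asarray(state[f"l{i}.W"], float)
            l.b = np.asarray(state[f"l{i}.b"], float)


class Adam:
    """Adam with the standard defaults (lr 1e-3, beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean CE over rows for integer ``targets``; returns (loss, dlogits).

    ``dlogits`` is the gradient of the SUM over rows (caller scales).
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(probs[np.arange(n), targets] + 1e-300).mean()
    grad = probs.copy()
    grad[np.arange(n), targets] -= 1.0
    return loss, grad / n
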