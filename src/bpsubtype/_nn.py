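"""Minimal feed-forward softmax networks trained with Adam.

Shared by the patch-classification head and the 6-input fusion MLP.
Pure numpy: forward pass, softmax cross-entropy backward pass, Adam
updates, optional weighted minibatch sampling with replacement, and an
end-of-epoch callback for checkpoint selection.  Deterministic for a
fixed RNG.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["SoftmaxNet"]


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxNet:
    """Fully connected net: ``in_dim -> hidden... -> n_classes`` with ReLU
    between layers and a softmax output.  ``hidden=()`` is multinomial
    logistic regression."""

    def __init__(
        self,
        in_dim: int,
        n_classes: int,
        hidden: Sequence[int] = (),
        seed: int = 0,
    ) -> None:
        self.in_dim = in_dim
        self.n_classes = n_classes
        self.hidden = tuple(hidden)
        rng = np.random.default_rng(seed)
        dims = [in_dim, *self.hidden, n_classes]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=np.float64)
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return _softmax(a @ self.W[-1] + self.b[-1])

    # -- parameters ---------------------------------------------------------
    def get_params(self) -> list[np.ndarray]:
        return [w.copy() for w in self.W] + [b.copy() for b in self.b]

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [p.copy() for p in params[:n]]
        self.b = [p.copy() for p in params[n:]]

    # -- training -----------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 15,
        batch_size: int = 64,
        lr: float = 1e-4,
        sample_weights: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        on_epoch_end: Callable[[int, "SoftmaxNet"], None] | None = None,
    ) -> None:
        """Minimize softmax cross-entropy with Adam.

        When ``sample_weights`` is given, each epoch draws ``len(X)``
        indices with replacement with probability proportional to the
        weights (a weighted random sampler); otherwise each epoch is a
        plain shuffled pass over the data.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n = len(X)
        if rng is None:
            rng = np.random.default_rng(0)
        probs = None
        if sample_weights is not None:
            probs = np.asarray(sample_weights, dtype=np.float64)
            probs = probs / probs.sum()

        params = self.W + self.b
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        for epoch in range(epochs):
            if probs is not None:
                order = rng.choice(n, size=n, replace=True, p=probs)
            else:
                order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                grads = self._backward(xb, yb)
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**t)
                    vhat = vi / (1 - beta2**t)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
            if on_epoch_end is not None:
                on_epoch_end(epoch, self)

    def _backward(self, xb: np.ndarray, yb: np.ndarray) -> list[np.ndarray]:
        # forward with caches
        acts = [xb]
        a = xb
        for W, b in zip(self.W[:-1], self.b[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            acts.append(a)
        p = _softmax(a @ self.W[-1] + self.b[-1])
        if not np.all(np.isfinite(p)):
            raise FloatingPointError("non-finite activations during training")
        B = len(xb)
        delta = p
        delta[np.arange(B), yb] -= 1.0
        delta /= B
        gW: list[np.ndarray] = [None] * len(self.W)  # type: ignore[list-item]
        gb: list[np.ndarray] = [None] * len(self.b)  # type: ignore[list-item]
        for l in range(len(self.W) - 1, -1, -1):
            gW[l] = acts[l].T @ delta
            gb[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ self.W[l].T) * (acts[l] > 0)
        return gW + gb
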