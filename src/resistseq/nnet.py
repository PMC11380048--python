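"""A small fully connected binary classifier trained with Adam.

Architecture: ``n_hidden_layers`` dense layers of ``hidden_units`` ReLU
units each (inverted dropout after every hidden layer during training),
followed by a single sigmoid output. Trained by mini-batch gradient
descent with the Adam update rule on binary cross-entropy. All
randomness — weight initialization, batch shuffling, dropout masks —
comes from one seeded generator, so training is deterministic.

The final hidden layer's activations are exposed for embedding
visualizations of what the trained network represents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import TrainingError

_EPS = 1e-7  # probability clamp inside the cross-entropy


@dataclass
class MLP:
    """Weights and forward/backward passes of the dense network."""

    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    dropout: float = 0.0
    final_loss: float = float("nan")

    @classmethod
    def init(
        cls,
        n_features: int,
        n_hidden_layers: int,
        hidden_units: int,
        dropout: float,
        rng: np.random.Generator,
    ) -> "MLP":
        sizes = [n_features] + [hidden_units] * n_hidden_layers + [1]
        weights, biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to the ReLU hidden stack
            scale = np.sqrt(2.0 / fan_in)
            weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights=weights, biases=biases, dropout=dropout)

    # -- forward ---------------------------------------------------------
    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[list[np.ndarray], np.ndarray]:
        """Return hidden activations (post-dropout when training) and output."""
        activations = []
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
            if rng is not None and self.dropout > 0.0:
                mask = rng.random(a.shape) >= self.dropout
                a = a * mask / (1.0 - self.dropout)
            activations.append(a)
        z = a @ self.weights[-1] + self.biases[-1]
        prob = expit(z)
        return activations, prob.ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid output probabilities; dropout disabled."""
        return self._forward(np.asarray(X, dtype=float))[1]

    def hidden_embedding(self, X: np.ndarray) -> np.ndarray:
        """Activations of the last hidden layer (samples x hidden_units)."""
        return self._forward(np.asarray(X, dtype=float))[0][-1]

    # -- training --------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        learning_rate: float,
        batch_size: int,
        epochs: int,
        rng: np.random.Generator,
        beta1: float = 0.9,
        beta2: float = 0.999,
        adam_eps: float = 1e-8,
    ) -> "MLP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = len(y)
        params = self.weights + self.biases
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                batch = order[start : start + batch_size]
                Xb, yb = X[batch], y[batch]
                grads = self._gradients(Xb, yb, rng)
                step += 1
                lr_t = learning_rate * (
                    np.sqrt(1.0 - beta2**step) / (1.0 - beta1**step)
                )
                for i, (p, g) in enumerate(zip(params, grads)):
                    m_t[i] = beta1 * m_t[i] + (1.0 - beta1) * g
                    v_t[i] = beta2 * v_t[i] + (1.0 - beta2) * g * g
                    p -= lr_t * m_t[i] / (np.sqrt(v_t[i]) + adam_eps)
        prob = self.predict_proba(X)
        self.final_loss = float(binary_cross_entropy(y, prob))
        if not np.isfinite(self.final_loss):
            raise TrainingError("training diverged: non-finite loss")
        return self

    def _gradients(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> list[np.ndarray]:
        n = len(y)
        # forward with dropout; cache activations and d(hidden)/d(pre-activation)
        acts = [X]
        local_grads: list[np.ndarray] = []
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            pre = a @ W + b
            relu_grad = (pre > 0.0).astype(float)
            a = np.maximum(pre, 0.0)
            if self.dropout > 0.0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
                relu_grad = relu_grad * mask
            local_grads.append(relu_grad)
            acts.append(a)
        z = acts[-1] @ self.weights[-1] + self.biases[-1]
        prob = expit(z.ravel())

        # BCE + sigmoid gives delta = prob - y at the output
        delta = ((prob - y) / n)[:, None]
        grads_w: list[np.ndarray] = []
        grads_b: list[np.ndarray] = []
        for layer in range(len(self.weights) - 1, -1, -1):
            grads_w.append(acts[layer].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if layer > 0:
                delta = (delta @ self.weights[layer].T) * local_grads[layer - 1]
        grads_w.reverse()
        grads_b.reverse()
        return grads_w + grads_b


def binary_cross_entropy(y: np.ndarray, prob: np.ndarray) -> float:
    """Mean binary cross-entropy with probability clamping."""
    p = np.clip(prob, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
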