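"""Feed-forward classifier for microbe-disease pair features.

Architecture 128 -> 100 -> 100 -> 50 -> 1 by default: ReLU hidden layers
with inverted dropout, a single sigmoid output unit, binary cross-entropy
loss, mini-batch Adam.  Implemented directly in NumPy with hand-derived
backpropagation; determinism is part of the contract (same seed, same
weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DnnConfig", "DnnModel", "build_dnn", "train_dnn", "predict_scores"]


@dataclass
class DnnConfig:
    layer_sizes: tuple[int, ...] = (128, 100, 100, 50, 1)
    learning_rate: float = 1e-3
    dropout: float = 0.2
    epochs: int = 300
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.layer_sizes[-1] != 1:
            raise ValueError("output layer must have a single unit")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class DnnModel:
    config: DnnConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def input_width(self) -> int:
        return self.config.layer_sizes[0]

    @property
    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)


def build_dnn(config: DnnConfig | None = None) -> DnnModel:
    """Seeded He-uniform initialisation of the configured architecture."""
    config = config or DnnConfig()
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    sizes = config.layer_sizes
    for din, dout in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / din)
        weights.append(rng.uniform(-limit, limit, size=(dout, din)))
        biases.append(np.zeros(dout))
    return DnnModel(config=config, weights=weights, biases=biases)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _forward(model: DnnModel, X: np.ndarray, dropout_rng=None):
    """Returns (probabilities, caches).  Dropout only when a generator is
    supplied (training); inference is deterministic."""
    p = model.config.dropout
    A = X
    caches = []
    n_layers = len(model.weights)
    for k, (W, b) in enumerate(zip(model.weights, model.biases)):
        Zpre = A @ W.T + b
        if k < n_layers - 1:
            H = np.maximum(Zpre, 0.0)
            if dropout_rng is not None and p > 0.0:
                keep = dropout_rng.random(H.shape) >= p
                H = H * keep / (1.0 - p)
            else:
                keep = None
            caches.append((A, Zpre, keep))
            A = H
        else:
            caches.append((A, Zpre, None))
            A = _sigmoid(Zpre)
    return A[:, 0], caches


def predict_scores(model: DnnModel, X: np.ndarray) -> np.ndarray:
    """Sigmoid scores, strictly inside (0, 1); dropout disabled."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_width:
        raise ValueError(
            f"feature width {X.shape[-1] if X.ndim == 2 else '?'} does not "
            f"match model input width {model.input_width}")
    probs, _ = _forward(model, X)
    return np.clip(probs, 1e-12, 1.0 - 1e-12)


def train_dnn(model: DnnModel, X: np.ndarray, y: np.ndarray,
              epochs: int | None = None) -> np.ndarray:
    """Minimise binary cross-entropy with mini-batch Adam; returns the
    per-epoch mean training loss.  Requires both classes present."""
    cfg = model.config
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != model.input_width:
        raise ValueError("feature width does not match model input width")
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all() or len(classes) < 2:
        raise ValueError("training labels must contain both classes 0 and 1")
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model, cfg.learning_rate)
    n = len(X)
    batch = min(cfg.batch_size, n)
    losses = np.empty(epochs)
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            Xb, yb = X[idx], y[idx]
            probs, caches = _forward(model, Xb, dropout_rng=rng)
            p = np.clip(probs, 1e-12, 1.0 - 1e-12)
            total += float(-(yb * np.log(p)
                             + (1 - yb) * np.log(1 - p)).sum())
            # dL/dZpre at the sigmoid output for mean BCE over the batch
            delta = ((probs - yb) / len(yb))[:, None]
            grads_W, grads_b = [], []
            for k in range(len(model.weights) - 1, -1, -1):
                A, Zpre, keep = caches[k]
                grads_W.append(delta.T @ A)
                grads_b.append(delta.sum(axis=0))
                if k > 0:
                    delta = delta @ model.weights[k]
                    _, Zprev, keep_prev = caches[k - 1]
                    relu_grad = (Zprev > 0).astype(float)
                    if keep_prev is not None:
                        relu_grad = relu_grad * keep_prev / (1.0 - cfg.dropout)
                    delta = delta * relu_grad
            grads_W.reverse()
            grads_b.reverse()
            opt.step(grads_W, grads_b)
        losses[epoch] = total / n
        if not np.isfinite(losses[epoch]):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
    return losses


class _Adam:
    def __init__(self, model: DnnModel, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model, self.lr = model, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(w) for w in model.weights]
        self.vW = [np.zeros_like(w) for w in model.weights]
        self.mb = [np.zeros_like(b) for b in model.biases]
        self.vb = [np.zeros_like(b) for b in model.biases]

    def step(self, grads_W, grads_b):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for i, (gW, gb) in enumerate(zip(grads_W, grads_b)):
            self.mW[i] = self.beta1 * self.mW[i] + (1 - self.beta1) * gW
            self.vW[i] = self.beta2 * self.vW[i] + (1 - self.beta2) * gW ** 2
            self.model.weights[i] -= self.lr * (self.mW[i] / b1c) / (
                np.sqrt(self.vW[i] / b2c) + self.eps)
            self.mb[i] = self.beta1 * self.mb[i] + (1 - self.beta1) * gb
            self.vb[i] = self.beta2 * self.vb[i] + (1 - self.beta2) * gb ** 2
            self.model.biases[i] -= self.lr * (self.mb[i] / b1c) / (
                np.sqrt(self.vb[i] / b2c) + self.eps)
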