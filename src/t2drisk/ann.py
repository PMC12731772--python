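"""Feed-forward multi-class classifier for normalized lifestyle features.

A small fully connected network (default 64-32-16 hidden units, ReLU hidden
activations, softmax output over the four risk classes) trained with the
Adam optimizer on categorical cross-entropy, with inverted dropout on the
hidden layers, an L2 weight penalty, Glorot-uniform initialization, and
early stopping on a stratified validation slice of the training partition
(patience in epochs, best weights restored).

Each neuron computes ``y_i = phi(sum_j w_ij x_j + b_i)``; see
:func:`dense_forward`.  The implementation is pure numpy so that a single
integer seed makes initialization, dropout, batch shuffling and hence the
fitted weights fully reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.model_selection import train_test_split

from .fuzzy import CLASS_ORDER

__all__ = [
    "ANNConfig",
    "FeedForwardClassifier",
    "dense_forward",
    "relu",
    "softmax",
    "stratified_split",
    "one_hot",
]


def relu(z):
    return np.maximum(z, 0.0)


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dense_forward(x, weights, biases, activation=None):
    """Single dense layer: ``y_i = phi(sum_j w_ij x_j + b_i)``.

    ``weights`` has shape (n_in, n_out); ``x`` is a vector or a batch of
    row vectors.  ``activation=None`` means the identity.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.shape[-1] != weights.shape[0]:
        raise ValueError(
            f"shape mismatch: inputs have {x.shape[-1]} features, "
            f"weights expect {weights.shape[0]}"
        )
    z = x @ weights + np.asarray(biases, dtype=float)
    return z if activation is None else activation(z)


def one_hot(labels, classes=CLASS_ORDER):
    """One-hot encode labels against a fixed class order."""
    classes = list(classes)
    labels = np.asarray(labels)
    idx = np.array([classes.index(l) for l in labels])
    out = np.zeros((len(labels), len(classes)))
    out[np.arange(len(labels)), idx] = 1.0
    return out


def stratified_split(n_or_labels, labels=None, train_frac=0.7, seed=0):
    """Deterministic stratified index split.

    ``stratified_split(labels)`` or ``stratified_split(n, labels)``; returns
    ``(train_idx, test_idx)`` with per-class proportions preserved within
    one record.  Every class must have at least 2 members.
    """
    if labels is None:
        labels = np.asarray(n_or_labels)
        n = len(labels)
    else:
        n = int(n_or_labels)
        labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(f"cannot stratify: class {thin[0]!r} has < 2 members")
    idx = np.arange(n)
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=labels, random_state=int(seed)
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass(frozen=True)
class ANNConfig:
    """Training and architecture configuration of the classifier."""

    hidden_sizes: tuple = (64, 32, 16)
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 150
    dropout: float = 0.2
    l2: float = 0.001
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def validate(self):
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        for name in ("dropout", "val_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning rate must lie in (0, 1)")


class FeedForwardClassifier:
    """ReLU/softmax network trained with Adam on categorical cross-entropy."""

    def __init__(self, config: ANNConfig | None = None, classes=CLASS_ORDER):
        self.config = config or ANNConfig()
        self.config.validate()
        self.classes = tuple(classes)
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.loss_history_: list[float] = []
        self.val_loss_history_: list[float] = []
        self.n_epochs_: int = 0

    # -- initialization ----------------------------------------------------
    def _init_params(self, n_features, rng):
        sizes = [n_features, *self.config.hidden_sizes, len(self.classes)]
        self.weights_, self.biases_ = [], []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights_.append(rng.uniform(-limit, limit, (fan_in, fan_out)))
            self.biases_.append(np.zeros(fan_out))

    # -- forward/backward --------------------------------------------------
    def _forward(self, X, rng=None):
        """Forward pass; dropout applied on hidden activations when rng given."""
        p = self.config.dropout
        acts, masks = [X], []
        a = X
        n_layers = len(self.weights_)
        for l, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = a @ W + b
            if l < n_layers - 1:
                a = relu(z)
                if rng is not None and p > 0:
                    mask = (rng.random(a.shape) >= p) / (1.0 - p)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = softmax(z)
            acts.append(a)
        return acts, masks

    def _loss(self, P, Y):
        eps = 1e-12
        return float(-np.mean(np.sum(Y * np.log(P + eps), axis=1)))

    def _backward(self, acts, masks, Y):
        B = Y.shape[0]
        l2 = self.config.l2
        grads_W, grads_b = [None] * len(self.weights_), [None] * len(self.weights_)
        delta = (acts[-1] - Y) / B  # softmax + cross-entropy gradient
        for l in range(len(self.weights_) - 1, -1, -1):
            a_prev = acts[l]
            grads_W[l] = a_prev.T @ delta + 2.0 * l2 * self.weights_[l]
            grads_b[l] = delta.sum(axis=0)
            if l > 0:
                delta = delta @ self.weights_[l].T
                if masks[l - 1] is not None:
                    delta = delta * masks[l - 1]
                delta = delta * (acts[l] > 0)
        return grads_W, grads_b

    # -- training ----------------------------------------------------------
    def fit(self, X, y) -> "FeedForwardClassifier":
        """Train on features ``X`` (rows in [0,1]) and class labels ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in training features")
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA22]))
        Y = one_hot(y, self.classes)

        if cfg.val_fraction > 0 and cfg.max_epochs > 0:
            tr_idx, val_idx = stratified_split(
                y, train_frac=1.0 - cfg.val_fraction, seed=cfg.seed + 1
            )
            X_tr, Y_tr = X[tr_idx], Y[tr_idx]
            X_val, Y_val = X[val_idx], Y[val_idx]
        else:
            X_tr, Y_tr, X_val, Y_val = X, Y, None, None

        self._init_params(X.shape[1], rng)
        # Adam state
        mW = [np.zeros_like(w) for w in self.weights_]
        vW = [np.zeros_like(w) for w in self.weights_]
        mb = [np.zeros_like(b) for b in self.biases_]
        vb = [np.zeros_like(b) for b in self.biases_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        best_val = np.inf
        best_params = None
        stall = 0
        n = X_tr.shape[0]
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                acts, masks = self._forward(X_tr[batch], rng=rng)
                epoch_loss += self._loss(acts[-1], Y_tr[batch]) * len(batch)
                gW, gb = self._backward(acts, masks, Y_tr[batch])
                t += 1
                for l in range(len(self.weights_)):
                    mW[l] = beta1 * mW[l] + (1 - beta1) * gW[l]
                    vW[l] = beta2 * vW[l] + (1 - beta2) * gW[l] ** 2
                    mb[l] = beta1 * mb[l] + (1 - beta1) * gb[l]
                    vb[l] = beta2 * vb[l] + (1 - beta2) * gb[l] ** 2
                    lr_t = cfg.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
                    self.weights_[l] -= lr_t * mW[l] / (np.sqrt(vW[l]) + eps)
                    self.biases_[l] -= lr_t * mb[l] / (np.sqrt(vb[l]) + eps)
            self.loss_history_.append(epoch_loss / n)
            self.n_epochs_ = epoch + 1
            if X_val is not None:
                val_loss = self._loss(self.predict_proba(X_val), Y_val)
                self.val_loss_history_.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = (
                        [w.copy() for w in self.weights_],
                        [b.copy() for b in self.biases_],
                    )
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_params is not None:
            self.weights_, self.biases_ = best_params
        return self

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        """Row-stochastic class-probability matrix (no dropout at inference)."""
        X = np.asarray(X, dtype=float)
        if self.weights_ is None:
            raise RuntimeError("classifier is not fitted")
        if X.shape[-1] != self.weights_[0].shape[0]:
            raise ValueError(
                f"expected {self.weights_[0].shape[0]} features, got {X.shape[-1]}"
            )
        acts, _ = self._forward(X, rng=None)
        return acts[-1]

    def predict(self, X) -> np.ndarray:
        P = self.predict_proba(X)
        return np.asarray(self.classes, dtype=object)[P.argmax(axis=1)]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "classes": list(self.classes),
            "weights": [w.tolist() for w in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
            "n_epochs": self.n_epochs_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeedForwardClassifier":
        cfg = d["config"]
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        model = cls(ANNConfig(**cfg), classes=d["classes"])
        model.weights_ = [np.asarray(w) for w in d["weights"]]
        model.biases_ = [np.asarray(b) for b in d["biases"]]
        model.n_epochs_ = d.get("n_epochs", 0)
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "FeedForwardClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
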