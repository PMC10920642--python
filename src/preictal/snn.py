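"""A shallow feed-forward network for binary preictal classification.

Architecture: input -> dropout(0.5) -> fully connected hidden layer (ReLU)
-> sigmoid output, trained full-batch with Adam (learning rate 3e-4) on the
binary cross-entropy loss for at most 500 epochs, with early stopping
(patience 50 epochs) on a held-out validation split; the best-validation
weights are restored.  Implemented directly in NumPy: the model is two
weight matrices, and a framework would add nothing but weight here.

All randomness (initialization, dropout masks) comes from a single seeded
generator, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ShallowNet:
    """Dropout-regularized single-hidden-layer classifier."""

    hidden_units: int = 32
    dropout: float = 0.5
    learning_rate: float = 3e-4
    max_epochs: int = 500
    patience: int = 50
    validation_fraction: float = 0.2
    seed: int = 0

    n_epochs_: int = field(init=False, default=0)
    history_: list = field(init=False, default_factory=list)

    def _init_params(self, n_in: int, rng: np.random.Generator) -> None:
        h = self.hidden_units
        self.W1 = rng.standard_normal((n_in, h)) * np.sqrt(2.0 / n_in)
        self.b1 = np.zeros(h)
        self.W2 = rng.standard_normal((h, 1)) * np.sqrt(2.0 / h)
        self.b2 = np.zeros(1)

    def _forward(self, X: np.ndarray, rng: np.random.Generator | None):
        if rng is not None and self.dropout > 0:
            mask = (rng.random(X.shape) >= self.dropout) / (1.0 - self.dropout)
            Xd = X * mask
        else:
            Xd = X
        z1 = Xd @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        p = _sigmoid(a1 @ self.W2 + self.b2)[:, 0]
        return Xd, z1, a1, p

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, _EPS, 1.0 - _EPS)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShallowNet":
        """Train on time-ordered rows; the trailing ``validation_fraction``
        of rows is held out for early stopping."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        n_val = max(1, int(round(n * self.validation_fraction))) if n > 4 else 0
        if n_val:
            X_tr, y_tr = X[:-n_val], y[:-n_val]
            X_val, y_val = X[-n_val:], y[-n_val:]
        else:
            X_tr, y_tr, X_val, y_val = X, y, X, y
        self._init_params(X.shape[1], rng)

        params = ["W1", "b1", "W2", "b2"]
        m = {k: np.zeros_like(getattr(self, k)) for k in params}
        v = {k: np.zeros_like(getattr(self, k)) for k in params}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_loss = np.inf
        best_weights = None
        best_epoch = 0
        n_tr = X_tr.shape[0]
        self.history_ = []

        for epoch in range(1, self.max_epochs + 1):
            Xd, z1, a1, p = self._forward(X_tr, rng)
            # BCE gradient wrt pre-sigmoid logit is (p - y) / n
            dlogit = (p - y_tr)[:, None] / n_tr
            grads = {
                "W2": a1.T @ dlogit,
                "b2": dlogit.sum(axis=0),
            }
            da1 = dlogit @ self.W2.T
            dz1 = da1 * (z1 > 0)
            grads["W1"] = Xd.T @ dz1
            grads["b1"] = dz1.sum(axis=0)
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1**epoch)
                vhat = v[k] / (1 - beta2**epoch)
                setattr(
                    self,
                    k,
                    getattr(self, k) - self.learning_rate * mhat / (np.sqrt(vhat) + eps),
                )
            val_loss = self._bce(self.predict_proba(X_val), y_val)
            self.history_.append(val_loss)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best_weights = {k: getattr(self, k).copy() for k in params}
                best_epoch = epoch
            elif epoch - best_epoch >= self.patience:
                break
        self.n_epochs_ = epoch
        if best_weights is not None:
            for k, w in best_weights.items():
                setattr(self, k, w)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Preictal probability per row (dropout disabled)."""
        X = np.asarray(X, dtype=float)
        return self._forward(X, None)[3]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)
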