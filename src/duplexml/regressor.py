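"""Convolutional regressor for descriptor matrices.

The network is the smallest architecture consistent with the design: a
single convolution layer whose kernel spans the full matrix height
(``N × 4``, stride 1, ReLU), a flatten, and a feed-forward head with two
hidden layers of 256 and 128 ReLU units and a linear scalar output.
Dropout follows the convolution and each hidden layer.  Weights use
Xavier (Glorot uniform) initialization; training minimizes mean squared
error with Adam on an 8:2 train/validation split, with early stopping on
the validation loss and restoration of the best-validation weights.

Strand-displacement samples are pairs of matrices; the same convolution
is applied to both and the flattened outputs are concatenated before the
feed-forward head.

Implemented directly on numpy (forward and backward passes are exact and
fully deterministic given the seed), wrapped as a scikit-learn estimator.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ConvNetRegressor", "TrainingError"]


class TrainingError(RuntimeError):
    """Raised on invalid training inputs or numerical failure (NaN loss)."""


def _glorot(rng, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


class ConvNetRegressor(RegressorMixin, BaseEstimator):
    """CNN + feed-forward regressor for (batches of) descriptor matrices.

    Default training recipe: ``batch_size=999``
    effectively trains full-batch on datasets of a few hundred samples;
    ``learning_rate=0.001`` with Adam; 8:2 train/validation split; early
    stopping.  ``n_filters``, hidden sizes, dropout rate and patience
    are configurable defaults.

    Input ``X`` has shape ``(n, rows, W)`` for single-matrix samples or
    ``(n, 2, rows, W)`` for two-matrix (strand-displacement) samples.

    Attributes set by :meth:`fit` (trailing underscore) include
    ``weights_``, ``history_`` (per-epoch train/validation MSE) and
    ``best_epoch_``.
    """

    def __init__(
        self,
        n_filters: int = 32,
        hidden_sizes: tuple = (256, 128),
        dropout: float = 0.2,
        learning_rate: float = 0.001,
        batch_size: int = 999,
        max_epochs: int = 250,
        patience: int = 25,
        val_fraction: float = 0.2,
        kernel_width: int = 4,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.kernel_width = kernel_width
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _coerce(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None, :, :]  # one channel/matrix per sample
        if X.ndim != 4:
            raise TrainingError(f"X must have 3 or 4 dimensions, got shape {X.shape}")
        return X

    def _conv_forward(self, X: np.ndarray, W_c, b_c, drop_rng=None):
        """X: (n, C, R, W) → flattened conv features (n, C*T*F) with cache."""
        n, C, R, W = X.shape
        kw = self.kernel_width
        T = W - kw + 1
        cols = sliding_window_view(X, kw, axis=3)  # (n, C, R, T, kw)
        cols = cols.transpose(0, 1, 3, 2, 4).reshape(n, C, T, R * kw)
        Z = cols @ W_c + b_c  # (n, C, T, F)
        A = np.maximum(Z, 0.0)
        mask = self._dropout_mask(A.shape, drop_rng)
        A = A * mask
        flat = A.reshape(n, -1)
        return flat, (cols, Z, mask)

    def _dropout_mask(self, shape, drop_rng):
        if drop_rng is None or self.dropout <= 0:
            return 1.0
        keep = 1.0 - self.dropout
        return (drop_rng.random(shape) < keep) / keep

    def _forward(self, X: np.ndarray, p: dict, drop_rng=None):
        flat, conv_cache = self._conv_forward(X, p["W_c"], p["b_c"], drop_rng)
        caches = [conv_cache]
        A = flat
        acts = [A]
        for h in range(len(self.hidden_sizes)):
            Z = A @ p[f"W{h}"] + p[f"b{h}"]
            A = np.maximum(Z, 0.0)
            mask = self._dropout_mask(A.shape, drop_rng)
            A = A * mask
            caches.append((Z, mask))
            acts.append(A)
        yhat = (A @ p["W_out"] + p["b_out"]).ravel()
        return yhat, (caches, acts)

    def _backward(self, X, y, p: dict, drop_rng):
        n = X.shape[0]
        yhat, (caches, acts) = self._forward(X, p, drop_rng)
        loss = float(np.mean((yhat - y) ** 2))
        grads = {}
        d = (2.0 / n) * (yhat - y)[:, None]  # (n, 1)
        A_last = acts[-1]
        grads["W_out"] = A_last.T @ d
        grads["b_out"] = d.sum(axis=0)
        dA = d @ p["W_out"].T
        for h in range(len(self.hidden_sizes) - 1, -1, -1):
            Z, mask = caches[1 + h]
            dZ = dA * mask * (Z > 0)
            grads[f"W{h}"] = acts[h].T @ dZ
            grads[f"b{h}"] = dZ.sum(axis=0)
            dA = dZ @ p[f"W{h}"].T
        cols, Z_c, mask_c = caches[0]
        n_, C, T, F = Z_c.shape
        dflat = dA.reshape(n_, C, T, F)
        dZc = dflat * mask_c * (Z_c > 0)
        grads["W_c"] = np.tensordot(cols, dZc, axes=([0, 1, 2], [0, 1, 2]))
        grads["b_c"] = dZc.sum(axis=(0, 1, 2))
        return loss, grads

    # ------------------------------------------------------------------ #

    def fit(self, X, y):
        X = self._coerce(X)
        y = np.asarray(y, dtype=float).ravel()
        n, C, R, W = X.shape
        if y.size != n:
            raise TrainingError(f"{n} samples but {y.size} labels")
        if n < 10:
            raise TrainingError(f"need at least 10 samples, got {n}")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise TrainingError("non-finite values in training data")

        rng = np.random.default_rng(self.random_state)
        kw = self.kernel_width
        if W < kw:
            raise TrainingError(f"matrix width {W} smaller than kernel width {kw}")
        T = W - kw + 1
        F = self.n_filters
        feat_dim = C * T * F

        p: dict[str, np.ndarray] = {
            "W_c": _glorot(rng, R * kw, F, (R * kw, F)),
            "b_c": np.zeros(F),
        }
        prev = feat_dim
        for h, width in enumerate(self.hidden_sizes):
            p[f"W{h}"] = _glorot(rng, prev, width, (prev, width))
            p[f"b{h}"] = np.zeros(width)
            prev = width
        p["W_out"] = _glorot(rng, prev, 1, (prev, 1))
        p["b_out"] = np.zeros(1)

        perm = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise TrainingError("validation split leaves no training samples")
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_val, y_val = X[val_idx], y[val_idx]

        optimizer = _Adam(p, self.learning_rate)
        history = []
        best_val = np.inf
        best_weights = {k: v.copy() for k, v in p.items()}
        best_epoch = 0
        wait = 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx.size)
            epoch_loss = 0.0
            for start in range(0, order.size, self.batch_size):
                batch = order[start : start + self.batch_size]
                loss, grads = self._backward(X_tr[batch], y_tr[batch], p, rng)
                if not np.isfinite(loss):
                    raise TrainingError(f"non-finite loss at epoch {epoch}")
                optimizer.step(p, grads)
                epoch_loss += loss * batch.size
            train_mse = epoch_loss / order.size
            val_pred, _ = self._forward(X_val, p)
            val_mse = float(np.mean((val_pred - y_val) ** 2))
            history.append((epoch, train_mse, val_mse))
            if val_mse < best_val:
                best_val = val_mse
                best_weights = {k: v.copy() for k, v in p.items()}
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break

        self.weights_ = best_weights
        self.best_epoch_ = best_epoch
        self.best_val_mse_ = best_val
        self.history_ = pd.DataFrame(history, columns=["epoch", "train_mse", "val_mse"])
        self.input_shape_ = (C, R, W)
        self.n_features_in_ = C * R * W
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = self._coerce(X)
        if X.shape[1:] != self.input_shape_:
            raise TrainingError(
                f"input shape {X.shape[1:]} does not match training shape "
                f"{self.input_shape_}"
            )
        yhat, _ = self._forward(X, self.weights_)  # dropout disabled
        return yhat

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        """Serialize hyperparameters and fitted weights to an ``.npz``."""
        check_is_fitted(self, "weights_")
        meta = json.dumps(
            {"params": self.get_params(), "input_shape": list(self.input_shape_)}
        )
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            **self.weights_,
        )

    @classmethod
    def load(cls, path) -> "ConvNetRegressor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = meta["params"]
            params["hidden_sizes"] = tuple(params["hidden_sizes"])
            model = cls(**params)
            model.weights_ = {
                k: data[k] for k in data.files if k != "__meta__"
            }
            model.input_shape_ = tuple(meta["input_shape"])
        C, R, W = model.input_shape_
        model.n_features_in_ = C * R * W
        return model
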