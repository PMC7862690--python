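"""Fully connected neural-network regressor for drug response.

A plain multilayer perceptron trained with Adam on mean-squared error,
with inverted dropout on the hidden layers and early stopping on a
held-out validation split (best-validation weights are restored). The
implementation is pure numpy, CPU-only and fully reproducible given a
seed, and follows the scikit-learn estimator contract so it composes with
sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .features import FeatureMatrix, NormalizationStats, ZScoreNormalizer

__all__ = ["FNNRegressor", "TrainedModel", "train_fnn", "predict"]

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
}

MIN_TRAIN_ROWS = 20


class FNNRegressor(BaseEstimator, RegressorMixin):
    """Feed-forward network regressor (MSE loss, Adam, early stopping).

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Widths of the hidden layers; at least one.
    activation : {"relu", "tanh"}
    dropout : float in [0, 1)
        Inverted-dropout rate applied to hidden activations during
        training only.
    learning_rate : float
        Adam step size.
    batch_size : int
    max_epochs : int
    patience : int
        Early stopping halts training after this many epochs without
        validation improvement; the best-validation weights are restored.
    validation_fraction : float in (0, 0.5]
        Fraction of the training rows held out for early stopping.
    random_state : int or None
        Seeds the validation split, weight init, batch shuffling and
        dropout masks; two fits with the same seed and data produce
        identical predictions.

    Attributes
    ----------
    coefs_, intercepts_ : per-layer weights and biases.
    loss_curve_, validation_scores_ : per-epoch training / validation MSE.
    best_epoch_ : epoch whose weights were restored.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (1024, 512, 256),
        activation: str = "relu",
        dropout: float = 0.1,
        learning_rate: float = 1e-4,
        batch_size: int = 32,
        max_epochs: int = 800,
        patience: int = 30,
        validation_fraction: float = 0.1,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_params_strict(self):
        if len(self.hidden_layer_sizes) < 1:
            raise ValueError("need at least one hidden layer")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 < self.validation_fraction <= 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5]")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def _coerce_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if hasattr(self, "feature_names_in_") and self.feature_names_in_ is not None:
                cols = list(X.columns)
                if cols != self.feature_names_in_:
                    missing = [c for c in self.feature_names_in_ if c not in set(cols)]
                    extra = [c for c in cols if c not in set(self.feature_names_in_)]
                    raise ValueError(
                        f"feature schema mismatch: missing={missing[:5]} extra={extra[:5]}"
                    )
            return X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)

    def _forward(self, X, rng=None):
        """Return (activations, pre-activations, dropout masks)."""
        act_f, _ = _ACTIVATIONS[self.activation]
        a = X
        acts, zs, masks = [a], [], []
        n_layers = len(self.coefs_)
        for i, (W, b) in enumerate(zip(self.coefs_, self.intercepts_)):
            z = a @ W + b
            zs.append(z)
            if i < n_layers - 1:
                a = act_f(z)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                    a = a * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                a = z  # linear output head
            acts.append(a)
        return acts, zs, masks

    def fit(self, X, y) -> "FNNRegressor":
        self._validate_params_strict()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
        else:
            self.feature_names_in_ = None
        Xa = self._coerce_X(X)
        ya = np.asarray(y, dtype=float).ravel()
        if Xa.ndim != 2 or len(Xa) != len(ya):
            raise ValueError("X must be 2-d and aligned with y")
        if len(Xa) < MIN_TRAIN_ROWS:
            raise ValueError(f"need at least {MIN_TRAIN_ROWS} training rows, got {len(Xa)}")
        if not (np.isfinite(Xa).all() and np.isfinite(ya).all()):
            raise ValueError("X and y must be finite (no NaN/inf)")
        self.n_features_in_ = Xa.shape[1]

        rng = np.random.default_rng(self.random_state)
        n = len(Xa)
        n_val = max(1, int(round(self.validation_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = Xa[tr_idx], ya[tr_idx]
        Xval, yval = Xa[val_idx], ya[val_idx]

        dims = [self.n_features_in_, *self.hidden_layer_sizes, 1]
        self.coefs_ = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.intercepts_ = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

        m_w = [np.zeros_like(W) for W in self.coefs_]
        v_w = [np.zeros_like(W) for W in self.coefs_]
        m_b = [np.zeros_like(b) for b in self.intercepts_]
        v_b = [np.zeros_like(b) for b in self.intercepts_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        _, act_grad = _ACTIVATIONS[self.activation]
        best_val = np.inf
        best_weights = None
        wait = 0
        self.loss_curve_ = []
        self.validation_scores_ = []
        self.best_epoch_ = 0

        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(len(Xtr))
            epoch_losses = []
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                acts, zs, masks = self._forward(xb, rng=rng)
                pred = acts[-1].ravel()
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"NaN/inf training loss at epoch {epoch}; "
                        "lower the learning rate or check the inputs"
                    )
                epoch_losses.append(loss)
                # backprop
                delta = (2.0 * err / len(yb))[:, None]
                t += 1
                for i in range(len(self.coefs_) - 1, -1, -1):
                    a_prev = acts[i]
                    gW = a_prev.T @ delta
                    gb = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.coefs_[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * act_grad(zs[i - 1], acts[i])
                    # Adam update
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gW
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gW**2
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb**2
                    mh_w = m_w[i] / (1 - beta1**t)
                    vh_w = v_w[i] / (1 - beta2**t)
                    mh_b = m_b[i] / (1 - beta1**t)
                    vh_b = v_b[i] / (1 - beta2**t)
                    self.coefs_[i] -= self.learning_rate * mh_w / (np.sqrt(vh_w) + eps)
                    self.intercepts_[i] -= self.learning_rate * mh_b / (np.sqrt(vh_b) + eps)
            self.loss_curve_.append(float(np.mean(epoch_losses)))
            val_pred = self._forward(Xval)[0][-1].ravel()
            val_loss = float(np.mean((val_pred - yval) ** 2))
            self.validation_scores_.append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                best_weights = (
                    [W.copy() for W in self.coefs_],
                    [b.copy() for b in self.intercepts_],
                )
                self.best_epoch_ = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.patience:
                    break
        if best_weights is not None:
            self.coefs_, self.intercepts_ = best_weights
        self.n_epochs_ = len(self.loss_curve_)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coefs_"):
            raise RuntimeError("FNNRegressor is not fitted")
        Xa = self._coerce_X(X)
        if Xa.shape[0] == 0:
            return np.empty(0)
        if Xa.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {Xa.shape[1]} features, model expects {self.n_features_in_}"
            )
        return self._forward(Xa)[0][-1].ravel()

    @property
    def n_parameters_(self) -> int:
        return int(
            sum(W.size for W in self.coefs_) + sum(b.size for b in self.intercepts_)
        )


# ---------------------------------------------------------------------------
# trained-model bundle (weights + schema + normalization stats)


@dataclass
class TrainedModel:
    """A fitted regressor plus everything needed to predict new pairs:
    the feature schema and the training-fold normalisation statistics."""

    regressor: FNNRegressor
    stats: NormalizationStats | None
    schema: list

    def predict(self, matrix: FeatureMatrix) -> np.ndarray:
        cols = list(matrix.X.columns)
        missing = [c for c in self.schema if c not in set(cols)]
        if missing:
            raise ValueError(f"feature schema mismatch; missing columns: {missing[:5]}")
        X = matrix.X
        if self.stats is not None:
            X = (X[self.stats.mean.index] - self.stats.mean) / self.stats.scale
        else:
            X = X[[c for c in self.schema]]
        return self.regressor.predict(X)

    # -- persistence -----------------------------------------------------
    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "weights.npz",
            **{f"W{i}": W for i, W in enumerate(self.regressor.coefs_)},
            **{f"b{i}": b for i, b in enumerate(self.regressor.intercepts_)},
        )
        with open(directory / "config.json", "w") as fh:
            json.dump(self.regressor.get_params(), fh, indent=1, default=list)
        schema_df = pd.DataFrame(
            [c if isinstance(c, tuple) else ("", c) for c in self.schema],
            columns=["block", "feature"],
        )
        schema_df.to_csv(directory / "schema.tsv", sep="\t", index=False)
        if self.stats is not None:
            self.stats.to_tsv(directory / "stats.tsv")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            params = json.load(fh)
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        reg = FNNRegressor(**params)
        data = np.load(directory / "weights.npz")
        n_layers = sum(1 for k in data.files if k.startswith("W"))
        reg.coefs_ = [data[f"W{i}"] for i in range(n_layers)]
        reg.intercepts_ = [data[f"b{i}"] for i in range(n_layers)]
        reg.n_features_in_ = reg.coefs_[0].shape[0]
        schema_df = pd.read_csv(directory / "schema.tsv", sep="\t")
        schema = [tuple(r) for r in schema_df.to_numpy()]
        reg.feature_names_in_ = None
        stats = None
        stats_path = directory / "stats.tsv"
        if stats_path.exists():
            sdf = pd.read_csv(stats_path, sep="\t", index_col=[0, 1])
            stats = NormalizationStats(mean=sdf["mean"], scale=sdf["scale"])
        return cls(regressor=reg, stats=stats, schema=schema)


def train_fnn(
    matrix: FeatureMatrix, normalize: bool = True, **fnn_params
) -> TrainedModel:
    """Fit normalisation stats and the FNN on an assembled feature matrix."""
    if matrix.y is None:
        raise ValueError("feature matrix has no response column")
    stats = None
    X = matrix.X
    if normalize:
        norm = ZScoreNormalizer().fit(X)
        X = norm.transform(X)
        stats = norm.stats_
    reg = FNNRegressor(**fnn_params)
    reg.fit(X, matrix.y.to_numpy())
    reg.feature_names_in_ = None  # schema enforced at the TrainedModel level
    return TrainedModel(regressor=reg, stats=stats, schema=list(matrix.X.columns))


def predict(model: TrainedModel, matrix: FeatureMatrix) -> np.ndarray:
    """Functional wrapper over :meth:`TrainedModel.predict`."""
    return model.predict(matrix)
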