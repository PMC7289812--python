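"""Neural-network surrogate for simulated hemodynamic metrics.

The regressor is a fully connected network with a single hidden layer of
ten ReLU units and a linear output, trained with the Adam optimizer on a
mean-squared-error loss, with early stopping once the monitored MSE stops
decreasing.  Inputs are standardized to zero mean and unit standard
deviation (population convention, sd over n) using training-set statistics;
the target is standardized internally for optimizer conditioning and
predictions are returned on the raw scale.

Evaluation utilities: Pearson correlation between predicted and simulated
values, Bland-Altman agreement statistics (bias and 1.96 sd limits, sample
sd convention), mean absolute error, and seeded 5-fold cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "HIDDEN_UNITS",
    "TrainConfig",
    "Scaler",
    "SurrogateModel",
    "DegenerateFeatureError",
    "standardize",
    "train",
    "predict",
    "pearson_r",
    "bland_altman",
    "mae",
    "kfold_cv",
]

HIDDEN_UNITS = 10


class DegenerateFeatureError(ValueError):
    """A feature column has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings.

    Full-batch Adam with a cosine-decayed step size, a small L2 penalty
    (keeps the interpolant smooth between training points), and a few
    seeded restarts keeping the lowest monitored loss; all derived from the
    fixed seed, so training is deterministic.
    """

    learning_rate: float = 1e-2
    lr_min: float = 1e-5
    max_epochs: int = 5000
    patience: int = 250
    min_delta: float = 0.0
    weight_decay: float = 1e-3
    restarts: int = 3
    hidden_units: int = HIDDEN_UNITS


@dataclass
class Scaler:
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def standardize(X, feature_names=None, allow_constant: bool = False):
    """Column-wise standardization to mean 0, sd 1 (population sd).

    Returns (X_std, Scaler); the scaler is retained so test data can be
    transformed with the training statistics.  A zero-variance column is an
    error unless ``allow_constant``, in which case it is centered to zero
    and left unscaled (it carries no information for the fit).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population convention (divide by n)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        if not allow_constant:
            names = (
                [feature_names[b] for b in bad]
                if feature_names is not None
                else list(bad)
            )
            raise DegenerateFeatureError(f"zero-variance feature column(s): {names}")
        sd = sd.copy()
        sd[bad] = 1.0
    scaler = Scaler(mean=mean, sd=sd)
    return scaler.transform(X), scaler


def _init_weights(n_in: int, n_hidden: int, rng: np.random.Generator):
    """Seeded He-style uniform initialization."""
    lim1 = np.sqrt(6.0 / n_in)
    lim2 = np.sqrt(6.0 / n_hidden)
    W1 = rng.uniform(-lim1, lim1, size=(n_in, n_hidden))
    b1 = np.zeros(n_hidden)
    W2 = rng.uniform(-lim2, lim2, size=(n_hidden, 1))
    b2 = np.zeros(1)
    return W1, b1, W2, b2


@dataclass
class SurrogateModel:
    """Trained 10-unit single-hidden-layer ReLU network plus its scalers."""

    feature_names: list
    target_name: str
    x_scaler: Scaler
    y_mean: float
    y_sd: float
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns "
                f"({self.feature_names}), got shape {X.shape}"
            )
        Z = self.x_scaler.transform(X)
        H = np.maximum(Z @ self.W1 + self.b1, 0.0)
        y_std = (H @ self.W2 + self.b2).ravel()
        return y_std * self.y_sd + self.y_mean

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "feature_names": self.feature_names,
            "target_name": self.target_name,
            "x_mean": self.x_scaler.mean.tolist(),
            "x_sd": self.x_scaler.sd.tolist(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "meta": self.meta,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "SurrogateModel":
        d = json.loads(doc)
        return cls(
            feature_names=d["feature_names"],
            target_name=d["target_name"],
            x_scaler=Scaler(np.array(d["x_mean"]), np.array(d["x_sd"])),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
            W1=np.array(d["W1"]),
            b1=np.array(d["b1"]),
            W2=np.array(d["W2"]),
            b2=np.array(d["b2"]),
            meta=d.get("meta", {}),
        )


def train(
    X,
    y,
    seed: int = 0,
    val: tuple | None = None,
    config: TrainConfig = TrainConfig(),
    feature_names=None,
    target_name: str = "target",
    allow_constant: bool = False,
) -> SurrogateModel:
    """Fit the surrogate by full-batch Adam on the MSE loss.

    Early stopping monitors the validation MSE when ``val=(X_val, y_val)``
    is given, otherwise the training MSE; training halts after ``patience``
    epochs without an improvement larger than ``min_delta``, and the best
    weights seen are kept.  Deterministic for a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one target per row")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(X.shape[1])]

    Z, scaler = standardize(X, feature_names, allow_constant=allow_constant)
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    t = (y - y_mean) / y_sd

    if val is not None:
        Xv, yv = val
        Zv = scaler.transform(np.asarray(Xv, dtype=float))
        tv = (np.asarray(yv, dtype=float).ravel() - y_mean) / y_sd

    rng = np.random.default_rng(seed)
    best = None
    best_loss = np.inf
    total_epochs = 0
    for _restart in range(max(config.restarts, 1)):
        params = list(_init_weights(X.shape[1], config.hidden_units, rng))
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        n = len(t)
        run_best = None
        run_best_loss = np.inf
        stale = 0
        for epoch in range(1, config.max_epochs + 1):
            frac = epoch / config.max_epochs
            lr = max(
                config.learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac)),
                config.lr_min,
            )
            A = Z @ params[0] + params[1]
            H = np.maximum(A, 0.0)
            pred = (H @ params[2] + params[3]).ravel()
            err = pred - t
            loss = float(err @ err) / n
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (non-finite loss)"
                )

            # backprop
            g_out = (2.0 / n) * err[:, None]
            gW2 = H.T @ g_out
            gb2 = g_out.sum(axis=0)
            g_h = (g_out @ params[2].T) * (A > 0)
            gW1 = Z.T @ g_h
            gb1 = g_h.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            for p_, g_, m_, v_ in zip(params, grads, m, v):
                g_ = g_ + config.weight_decay * p_
                m_ *= beta1
                m_ += (1 - beta1) * g_
                v_ *= beta2
                v_ += (1 - beta2) * g_**2
                mhat = m_ / (1 - beta1**epoch)
                vhat = v_ / (1 - beta2**epoch)
                p_ -= lr * mhat / (np.sqrt(vhat) + eps)

            if val is not None:
                Hv = np.maximum(Zv @ params[0] + params[1], 0.0)
                ev = (Hv @ params[2] + params[3]).ravel() - tv
                monitored = float(ev @ ev) / max(len(tv), 1)
            else:
                monitored = loss
            if monitored < run_best_loss - config.min_delta:
                run_best_loss = monitored
                run_best = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        total_epochs += epoch
        if run_best_loss < best_loss:
            best_loss = run_best_loss
            best = run_best

    epoch = total_epochs
    return SurrogateModel(
        feature_names=list(feature_names),
        target_name=target_name,
        x_scaler=scaler,
        y_mean=y_mean,
        y_sd=y_sd,
        W1=best[0],
        b1=best[1],
        W2=best[2],
        b2=best[3],
        meta={
            "seed": int(seed),
            "epochs": int(epoch),
            "final_mse": best_loss,
            "config": asdict(config),
        },
    )


def predict(model: SurrogateModel, X) -> np.ndarray:
    return model.predict(X)


def pearson_r(pred, true) -> float:
    """Sample Pearson correlation coefficient."""
    a = np.asarray(pred, dtype=float).ravel()
    b = np.asarray(true, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two aligned vectors with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(a, b)[0, 1])


def bland_altman(pred, true):
    """Agreement statistics: (bias, (lower, upper) 1.96 sd limits).

    bias = mean(pred - true); limits use the sample sd (n - 1)."""
    a = np.asarray(pred, dtype=float).ravel()
    b = np.asarray(true, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need two aligned vectors with n >= 3")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def mae(pred, true) -> float:
    a = np.asarray(pred, dtype=float).ravel()
    b = np.asarray(true, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 1:
        raise ValueError("need two aligned non-empty vectors")
    return float(np.mean(np.abs(a - b)))


def kfold_cv(
    X,
    y,
    k: int = 5,
    seed: int = 0,
    config: TrainConfig = TrainConfig(),
    feature_names=None,
    target_name: str = "target",
):
    """Seeded k-fold cross-validation; refits on all data after scoring.

    Returns (fold_mses, model): per-fold validation MSEs and the model
    refit on the full data with the same seed.
    """
    from sklearn.model_selection import KFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < k:
        raise ValueError(f"need at least k={k} rows, got {len(y)}")
    scores = []
    for tr, va in KFold(n_splits=k, shuffle=True, random_state=seed).split(X):
        mdl = train(
            X[tr], y[tr], seed=seed, val=(X[va], y[va]), config=config,
            feature_names=feature_names, target_name=target_name,
        )
        resid = mdl.predict(X[va]) - y[va]
        scores.append(float(np.mean(resid**2)))
    model = train(
        X, y, seed=seed, config=config,
        feature_names=feature_names, target_name=target_name,
    )
    return scores, model
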