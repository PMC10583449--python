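"""Train/test splitting, RF and MLR regression, and regression metrics.

All comparisons in the study share one random 80/20 split and one fixed set
of RF hyperparameters so that representation (descriptors vs fingerprint
bits), not modelling choices, drives metric differences. R-squared is
reported alongside RMSE/MAE but treated as secondary: it rewards model
complexity and is a weaker guide to predictive quality than the error
magnitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import StandardScaler

__all__ = [
    "SplitIndices",
    "ModelMetrics",
    "MLRModel",
    "split",
    "train_rf",
    "train_mlr",
    "evaluate",
]


@dataclass(frozen=True)
class SplitIndices:
    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self):
        tr, te = set(self.train_idx.tolist()), set(self.test_idx.tolist())
        if tr & te:
            raise ValueError("train/test indices overlap")
        n = len(tr) + len(te)
        if sorted(tr | te) != list(range(n)):
            raise ValueError("indices must partition 0..n-1")


def split(n_rows: int, fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Uniform random train/test partition; |train| = round(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(round(fraction * n_rows))
    return SplitIndices(
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
    )


@dataclass(frozen=True)
class ModelMetrics:
    """R^2 / RMSE / MAE for one (model, partition) pair. Errors in log units."""

    r2: float
    rmse: float
    mae: float
    partition: str
    n: int

    def __post_init__(self):
        if np.isfinite(self.rmse) and np.isfinite(self.mae):
            # rmse >= mae by Jensen; tiny fp slack
            if self.rmse < self.mae - 1e-12:
                raise ValueError("RMSE cannot be below MAE")

    def as_dict(self) -> dict:
        return {"partition": self.partition, "n": self.n, "r2": self.r2, "rmse": self.rmse, "mae": self.mae}


def evaluate(model, X, y, partition: str = "test") -> ModelMetrics:
    """Compute MAE, RMSE and R^2 of *model* on (X, y).

    MAE = mean |e|, RMSE = sqrt(mean e^2), R^2 = 1 - SSres/SStot. A constant
    target leaves R^2 undefined; it is reported as NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(model.predict(X), dtype=float)
    e = yhat - y
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        warnings.warn("constant target: R^2 undefined, reported as NaN", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(e**2)) / sstot
    return ModelMetrics(r2=r2, rmse=rmse, mae=mae, partition=partition, n=len(y))


def train_rf(
    X,
    y,
    n_estimators: int = 500,
    seed: int = 42,
    max_depth: int | None = None,
    **kwargs,
) -> RandomForestRegressor:
    """Fit a random-forest regressor with the study's fixed hyperparameters.

    Defaults: 500 trees, unlimited depth, the library's default feature
    subsampling, seed 42. The same settings are reused for every
    representation so models stay comparable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 training rows")
    rf = RandomForestRegressor(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed, **kwargs
    )
    rf.fit(X, y)
    return rf


class MLRModel:
    """Ordinary least squares on standardized features.

    Features are standardized internally (zero mean, unit variance;
    zero-variance columns pass through unscaled) and coefficients are
    reported on the standardized scale, retrievable by feature name.
    """

    def __init__(self, scaler: StandardScaler, lr: LinearRegression, feature_names: list[str]):
        self._scaler = scaler
        self._lr = lr
        self.feature_names = feature_names

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._lr.predict(self._scaler.transform(X))

    @property
    def intercept(self) -> float:
        return float(self._lr.intercept_)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self._lr.coef_, index=self.feature_names, name="coefficient")


def train_mlr(X, y, feature_names: list[str] | None = None) -> MLRModel:
    """Fit multiple linear regression (OLS) on standardized features.

    Raises on p >= n: an unregularized fit would be rank deficient.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p >= n:
        raise ValueError(f"rank deficiency: p={p} features >= n={n} rows (no regularization)")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(p)]
    scaler = StandardScaler().fit(X)
    lr = LinearRegression().fit(scaler.transform(X), y)
    return MLRModel(scaler, lr, list(feature_names))
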