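"""Carbon-density regression models (RF, DT, MLR) and fit metrics.

Three model families estimate plot/pixel carbon density from vegetation
indices: a random-forest regressor (100 trees, max depth 5, min samples to
split 3, seed 42), a single regression tree (max depth 4, min samples 3,
seed 42), and ordinary-least-squares multiple linear regression
y = b0 + b1 x1 + ... + bn xn.  Data are split 7:3 into training and test
sets by simple seeded random sampling.

Fit quality is summarised by five metrics:

    R^2   = 1 - sum (y - yhat)^2 / sum (y - ybar)^2
    RMSE  = sqrt(mean (y - yhat)^2)                       [t/ha]
    rRMSE = RMSE / ybar                                   [-]
    MAE   = mean |y - yhat|                               [t/ha]
    MBE   = mean (y - yhat)   (observed minus predicted)  [t/ha]

A positive MBE therefore means the model underpredicts.  An alternative
printed rRMSE form, sqrt(MSE / ybar), circulates in the applied literature
but is dimensionally inconsistent; it is available behind ``as_printed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.tree import DecisionTreeRegressor

from .raster import Raster

__all__ = ["ModelSpec", "MetricsReport", "FittedCarbonModel",
           "split_indices", "split_data", "fit", "evaluate",
           "predict_density_map"]

_RF_DEFAULTS = {"n_estimators": 100, "max_depth": 5,
                "min_samples_split": 3, "random_state": 42}
_DT_DEFAULTS = {"max_depth": 4, "min_samples_split": 3, "random_state": 42}


@dataclass(frozen=True)
class ModelSpec:
    """Model family, hyperparameters, predictors and the 7:3 split seed."""

    kind: str  # rf | dt | mlr
    predictor_names: tuple[str, ...] = ()
    hyperparameters: dict = field(default_factory=dict)
    split_fraction: float = 0.7
    split_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"rf", "dt", "mlr"}:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split fraction must lie in (0, 1)")

    def resolved_hyperparameters(self) -> dict:
        base = {"rf": _RF_DEFAULTS, "dt": _DT_DEFAULTS, "mlr": {}}[self.kind]
        return {**base, **self.hyperparameters}


@dataclass(frozen=True)
class MetricsReport:
    r2: float
    rmse: float
    rrmse: float
    mae: float
    mbe: float
    n: int


@dataclass
class FittedCarbonModel:
    """A trained density model with its predictor set and split metrics."""

    spec: ModelSpec
    predictor_names: tuple[str, ...]
    estimator: object | None = None          # rf/dt
    coefficients: np.ndarray | None = None   # mlr: (b0, b1, ..., bn)
    training_metrics: MetricsReport | None = None
    test_metrics: MetricsReport | None = None

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.predictor_names if p not in X.columns]
            if missing:
                raise KeyError(f"missing predictors: {missing}")
            X = X[list(self.predictor_names)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(self.predictor_names):
            raise ValueError(
                f"expected {len(self.predictor_names)} predictors, got {X.shape[1]}")
        if self.coefficients is not None:
            return self.coefficients[0] + X @ self.coefficients[1:]
        return self.estimator.predict(X)


def split_indices(n: int, fraction: float = 0.7, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Seeded simple random split: ceil(fraction*n) train, remainder test."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_train = math.ceil(fraction * n)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split_data(X: np.ndarray, y: np.ndarray, fraction: float = 0.7,
               seed: int = 0):
    """Split (X, y) into ((X_tr, y_tr), (X_te, y_te)) per ``split_indices``."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    tr, te = split_indices(len(y), fraction, seed)
    return (X[tr], y[tr]), (X[te], y[te])


def fit(spec: ModelSpec, X: np.ndarray | pd.DataFrame, y: np.ndarray,
        evaluate_split: bool = True) -> FittedCarbonModel:
    """Train the specified model; optionally fit on the 7:3 training subset
    and report train/test metrics.

    With ``evaluate_split=False`` the model is fit on all rows and only
    training metrics are reported.
    """
    if isinstance(X, pd.DataFrame):
        names = tuple(spec.predictor_names) or tuple(X.columns)
        X = X[list(names)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        names = tuple(spec.predictor_names) or tuple(
            f"x{i+1}" for i in range(X.shape[1]))
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per response value")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values must be removed before fitting")

    if evaluate_split:
        (X_tr, y_tr), (X_te, y_te) = split_data(
            X, y, spec.split_fraction, spec.split_seed)
    else:
        X_tr, y_tr = X, y
        X_te = y_te = None

    model = FittedCarbonModel(spec=spec, predictor_names=names)
    if spec.kind == "mlr":
        A = np.column_stack([np.ones(len(y_tr)), X_tr])
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            raise np.linalg.LinAlgError(
                f"rank-deficient design: rank {rank} < {A.shape[1]} columns; "
                f"remove collinear predictors before fitting MLR")
        coef, *_ = np.linalg.lstsq(A, y_tr, rcond=None)
        model.coefficients = coef
    else:
        hp = spec.resolved_hyperparameters()
        est = (RandomForestRegressor(**hp) if spec.kind == "rf"
               else DecisionTreeRegressor(**hp))
        est.fit(X_tr, y_tr)
        model.estimator = est

    model.training_metrics = evaluate(y_tr, model.predict(X_tr))
    if X_te is not None and len(y_te) >= 2:
        model.test_metrics = evaluate(y_te, model.predict(X_te))
    return model


def evaluate(y: np.ndarray, y_hat: np.ndarray,
             as_printed: bool = False) -> MetricsReport:
    """Five-metric fit report; see the module docstring for definitions."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be equal-length 1-D vectors")
    if y.size < 2:
        raise ValueError("evaluate needs at least 2 samples")
    ybar = y.mean()
    err = y - y_hat
    sse = float(err @ err)
    sst = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    mse = sse / y.size
    rmse = math.sqrt(mse)
    if ybar == 0:
        raise ZeroDivisionError("rRMSE undefined: mean observation is zero")
    rrmse = math.sqrt(mse / ybar) if as_printed else rmse / ybar
    return MetricsReport(
        r2=float(r2), rmse=rmse, rrmse=float(rrmse),
        mae=float(np.mean(np.abs(err))), mbe=float(err.mean()), n=int(y.size))


def predict_density_map(model: FittedCarbonModel,
                        vi_rasters: dict[str, Raster],
                        extent_mask: np.ndarray) -> tuple[Raster, int]:
    """Per-pixel density prediction inside the mask; nodata outside.

    Negative predictions are floored at 0 (carbon density is nonnegative);
    the number of floored pixels is returned alongside the map.
    """
    missing = [p for p in model.predictor_names if p not in vi_rasters]
    if missing:
        raise KeyError(f"predictor raster(s) missing: {missing}")
    first = vi_rasters[model.predictor_names[0]]
    shape = first.shape
    extent_mask = np.asarray(extent_mask, bool)
    if extent_mask.shape != shape:
        raise ValueError("extent mask shape does not match the predictor grids")
    valid = extent_mask.copy()
    for p in model.predictor_names:
        r = vi_rasters[p]
        if r.shape != shape:
            raise ValueError(f"predictor raster {p!r} is on a different grid")
        valid &= ~r.mask
    out = np.full(shape, np.nan)
    n_floored = 0
    if valid.any():
        X = np.column_stack([vi_rasters[p].data[valid]
                             for p in model.predictor_names])
        pred = model.predict(X)
        n_floored = int(np.sum(pred < 0))
        out[valid] = np.maximum(pred, 0.0)
    return Raster(out, first.grid, first.crs, ~valid), n_floored
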