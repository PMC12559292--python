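"""Gaussian maximum-likelihood land-cover classification and accuracy scoring.

Each land-cover class is modelled as a multivariate Gaussian over the band
reflectances (sample mean vector and covariance matrix from training
pixels; equal priors by default).  A pixel is assigned the class maximising
the Gaussian log-likelihood plus log prior; exact ties go to the lowest
class index.  Singular covariances are ridge-regularised (reported on the
model).  Map agreement is summarised by a confusion matrix, overall
accuracy OA = trace/n and Cohen's kappa = (p_o - p_e) / (1 - p_e) with the
chance agreement p_e from the marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster, RasterStack

__all__ = ["ClassModel", "ConfusionReport", "fit_mlc", "classify",
           "confusion", "sample_training_pixels"]


@dataclass
class ClassModel:
    label: int | str
    mean: np.ndarray
    covariance: np.ndarray
    prior: float = 1.0
    regularized: bool = False


@dataclass(frozen=True)
class ConfusionReport:
    matrix: pd.DataFrame  # rows = truth, columns = prediction
    overall_accuracy: float
    kappa: float
    n: int


def fit_mlc(training_pixels: dict[int | str, np.ndarray],
            priors: dict | None = None,
            ridge_scale: float = 1e-8) -> dict[int | str, ClassModel]:
    """Per-class sample mean and covariance from training band vectors.

    ``training_pixels`` maps class label -> (n_samples, n_bands) array; each
    class needs at least n_bands + 1 samples.  A singular covariance gets a
    ridge of ``ridge_scale * trace / n_bands`` added to its diagonal.
    """
    if not training_pixels:
        raise ValueError("no training classes provided")
    models: dict[int | str, ClassModel] = {}
    k = len(training_pixels)
    for label, X in training_pixels.items():
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"class {label!r}: training pixels must be 2-D")
        n, d = X.shape
        if n < d + 1:
            raise ValueError(
                f"class {label!r} has {n} samples; need at least {d + 1}")
        mean = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        regularized = False
        eps = ridge_scale * max(np.trace(cov), 1.0) / d
        for _ in range(40):
            try:
                np.linalg.cholesky(cov)
                break
            except np.linalg.LinAlgError:
                cov = cov + eps * np.eye(d)
                eps *= 10.0
                regularized = True
        else:
            raise np.linalg.LinAlgError(
                f"class {label!r}: covariance could not be regularised")
        if regularized:
            warnings.warn(f"class {label!r}: singular covariance ridge-regularised")
        prior = 1.0 / k if priors is None else float(priors[label])
        models[label] = ClassModel(label, mean, cov, prior, regularized)
    return models


def _log_gaussian(X: np.ndarray, model: ClassModel) -> np.ndarray:
    d = model.mean.size
    sign, logdet = np.linalg.slogdet(model.covariance)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            f"class {model.label!r}: covariance is not positive-definite")
    diff = X - model.mean
    sol = np.linalg.solve(model.covariance, diff.T).T
    maha = np.einsum("ij,ij->i", diff, sol)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def classify(stack: RasterStack, models: dict[int | str, ClassModel],
             band_order: list[str] | None = None) -> Raster:
    """Per-pixel MLC label map; nodata pixels keep the nodata label 0.

    Class labels must be positive integers (0 is reserved for nodata).
    Ties in the posterior go to the lowest class label.
    """
    labels = sorted(models)
    band_order = band_order or stack.band_names
    X = np.stack([stack.band(b) for b in band_order], axis=-1)
    valid = ~stack.nodata_mask
    Xv = X[valid].astype(float)
    scores = np.empty((Xv.shape[0], len(labels)))
    for j, lab in enumerate(labels):
        scores[:, j] = _log_gaussian(Xv, models[lab]) + np.log(models[lab].prior)
    best = np.argmax(scores, axis=1)  # argmax takes the first (lowest) label on ties
    out = np.zeros(stack.shape, dtype=int)
    out[valid] = np.asarray(labels)[best]
    return Raster(out, stack.grid, stack.crs, ~valid)


def confusion(pred, truth) -> ConfusionReport:
    """Confusion matrix, overall accuracy and kappa for two label maps.

    Accepts co-gridded categorical rasters or flat label vectors; pixels
    that are nodata in either raster are excluded.
    """
    if isinstance(pred, Raster) and isinstance(truth, Raster):
        keep = ~(pred.mask | truth.mask)
        p = pred.data[keep].ravel()
        t = truth.data[keep].ravel()
    else:
        p = np.asarray(pred).ravel()
        t = np.asarray(truth).ravel()
        if p.shape != t.shape:
            raise ValueError("prediction and truth must have equal length")
    labels = np.unique(np.concatenate([p, t]))
    index = {lab: i for i, lab in enumerate(labels)}
    k = len(labels)
    mat = np.zeros((k, k), dtype=int)
    for ti, pi in zip(t, p):
        mat[index[ti], index[pi]] += 1
    n = int(mat.sum())
    if n == 0:
        raise ValueError("no jointly valid pixels to compare")
    p_o = np.trace(mat) / n
    p_e = float(np.sum(mat.sum(axis=1) * mat.sum(axis=0))) / n ** 2
    kappa = 1.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    frame = pd.DataFrame(mat, index=labels, columns=labels)
    return ConfusionReport(matrix=frame, overall_accuracy=float(p_o),
                           kappa=float(kappa), n=n)


def sample_training_pixels(stack: RasterStack, truth: Raster,
                           n_per_class: int, seed: int,
                           band_order: list[str] | None = None
                           ) -> dict[int, np.ndarray]:
    """Seeded per-class random sample of band vectors from a truth map."""
    band_order = band_order or stack.band_names
    X = np.stack([stack.band(b) for b in band_order], axis=-1)
    valid = ~(stack.nodata_mask | truth.mask)
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for lab in np.unique(truth.data[valid]):
        idx = np.argwhere(valid & (truth.data == lab))
        take = min(n_per_class, len(idx))
        sel = idx[rng.choice(len(idx), size=take, replace=False)]
        out[int(lab)] = X[sel[:, 0], sel[:, 1]].astype(float)
    return out
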