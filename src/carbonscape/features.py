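"""Predictor screening: Pearson correlation ranking and VIF collinearity removal.

Candidate vegetation indices are first screened by the magnitude of their
product-moment correlation with observed carbon density (threshold on |r|,
default 0.5, with an optional top-k fallback so a selection always exists),
then pruned iteratively by variance inflation factor: the predictor with the
largest VIF is removed while any VIF exceeds the limit (default 10).
Rows with any missing predictor or response are dropped listwise first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CorrelationReport", "VifReport", "pearson_r",
           "screen_by_correlation", "vif_filter"]


@dataclass
class CorrelationReport:
    """Ranked correlations and the selection they imply."""

    table: pd.DataFrame   # columns: index, r, abs_r, n, rank, selected
    threshold: float
    top_k: int | None

    @property
    def selected(self) -> list[str]:
        return list(self.table.loc[self.table["selected"], "index"])


@dataclass
class VifReport:
    table: pd.DataFrame           # columns: index, vif, aux_r2 (retained set)
    removed: list[tuple[str, float]] = field(default_factory=list)  # (name, vif at removal)
    exact_collinear: list[str] = field(default_factory=list)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation r = S_xy / sqrt(S_xx S_yy).

    Requires equal-length vectors of at least 3 values; a constant vector
    has no defined correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("pearson_r needs at least 3 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def screen_by_correlation(candidates: dict[str, np.ndarray], y: np.ndarray,
                          threshold: float = 0.5,
                          top_k: int | None = None) -> CorrelationReport:
    """Rank candidates by |r| against the response and flag the selection.

    Selected are candidates with |r| >= threshold, optionally capped at
    ``top_k``; when no candidate clears the threshold and ``top_k`` is set,
    the top-k by |r| are selected instead (fallback), otherwise the
    selection is empty and a warning is emitted.  Ties in |r| keep the
    candidate registration order.
    """
    if not candidates:
        raise ValueError("screen_by_correlation needs at least one candidate")
    y = np.asarray(y, dtype=float)
    names = list(candidates)
    data = pd.DataFrame({n: np.asarray(v, float) for n, v in candidates.items()})
    data["__y__"] = y
    data = data.dropna(axis=0)
    rows = []
    for n in names:
        r = pearson_r(data[n].to_numpy(), data["__y__"].to_numpy())
        rows.append({"index": n, "r": r, "abs_r": abs(r), "n": len(data)})
    tab = pd.DataFrame(rows)
    # stable sort keeps registration order on |r| ties
    tab = tab.sort_values("abs_r", ascending=False, kind="stable").reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    passed = tab["abs_r"] >= threshold
    if passed.any():
        selected = passed.copy()
        if top_k is not None:
            selected &= tab["rank"] <= top_k
    elif top_k is not None:
        selected = tab["rank"] <= top_k
    else:
        warnings.warn("no candidate reached the correlation threshold; "
                      "selection is empty")
        selected = passed
    tab["selected"] = selected
    return CorrelationReport(table=tab, threshold=threshold, top_k=top_k)


def _aux_r2(X: np.ndarray, j: int) -> float:
    """R^2 of regressing column j on the remaining columns (with intercept)."""
    yj = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(yj)), others])
    coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
    resid = yj - A @ coef
    sst = float(np.sum((yj - yj.mean()) ** 2))
    if sst == 0.0:
        return 1.0
    return 1.0 - float(resid @ resid) / sst


def vif_filter(X: pd.DataFrame, limit: float = 10.0) -> tuple[VifReport, pd.DataFrame]:
    """Iteratively remove the worst-VIF predictor until all VIF <= limit.

    VIF_j = 1 / (1 - R_j^2) from the auxiliary regression of predictor j on
    the others.  An exactly collinear predictor (R_j^2 = 1) is removed as
    "exact collinearity", preferring to drop the later column.  With a
    single remaining column the VIF is reported as 1.
    """
    X = X.dropna(axis=0)
    cols = list(X.columns)
    if X.shape[0] <= len(cols):
        raise ValueError("vif_filter needs more rows than predictors")
    report = VifReport(table=pd.DataFrame())
    while True:
        if len(cols) <= 1:
            break
        M = X[cols].to_numpy(dtype=float)
        r2 = np.array([_aux_r2(M, j) for j in range(len(cols))])
        with np.errstate(divide="ignore"):
            vif = np.where(r2 >= 1.0 - 1e-12, np.inf, 1.0 / (1.0 - r2))
        if np.isinf(vif).any():
            # drop the later-ranked of the exactly collinear columns
            j = int(np.flatnonzero(np.isinf(vif))[-1])
            report.exact_collinear.append(cols[j])
            report.removed.append((cols[j], float("inf")))
            cols.pop(j)
            continue
        j = int(np.argmax(vif))
        if vif[j] <= limit:
            report.table = pd.DataFrame(
                {"index": cols, "vif": vif, "aux_r2": r2})
            break
        report.removed.append((cols[j], float(vif[j])))
        cols.pop(j)
    if len(cols) == 1:
        report.table = pd.DataFrame(
            {"index": cols, "vif": [1.0], "aux_r2": [0.0]})
    elif len(cols) == 0:
        report.table = pd.DataFrame({"index": [], "vif": [], "aux_r2": []})
    return report, X[cols]
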