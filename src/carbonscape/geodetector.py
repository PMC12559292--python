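"""Geographical detector: factor and interaction q-statistics.

The factor detector quantifies how much of the spatial variance of a
continuous variable (here carbon density) a categorical stratification
explains:

    q = 1 - SSW / SST = 1 - sum_h n_h sigma_h^2 / (n sigma^2)

where h indexes strata, sigma_h^2 is the within-stratum (population)
variance and sigma^2 the overall variance.  q = 0 means the strata explain
nothing; q = 1 means the variable is constant within every stratum.
Strata with fewer than 2 usable observations are excluded and reported.

The interaction detector evaluates q on the cross-classification of two
factors and assigns one of the five standard categories by comparing
q(A∩B) with q(A), q(B), their minimum/maximum and their sum:

    q_AB <  min(q_A, q_B)        -> "nonlinear weaken"
    min <= q_AB <= max           -> "univariate weaken"
    max <  q_AB <  q_A + q_B     -> "bivariate enhance"
    q_AB == q_A + q_B            -> "independent"
    q_AB >  q_A + q_B            -> "nonlinear enhance"

Continuous covariates (elevation, temperature, GDP, ...) are stratified
with ``discretize_continuous`` (quantile or equal-interval bins) before
detection.  No significance test is attached to q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["QResult", "factor_q", "interaction_q", "discretize_continuous"]

_EQ_TOL = 1e-9


@dataclass(frozen=True)
class QResult:
    q: float
    n: int
    strata: pd.DataFrame                 # columns: stratum, n_h, mean, var
    n_excluded_strata: int = 0
    n_excluded_values: int = 0
    q_a: float | None = None
    q_b: float | None = None
    interaction: str | None = None
    degenerate: bool = False


def _clean(values: np.ndarray, strata: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float).ravel()
    strata = np.asarray(strata).ravel()
    if values.shape != strata.shape:
        raise ValueError("values and strata must have equal length")
    keep = np.isfinite(values)
    if strata.dtype.kind == "f":
        keep &= np.isfinite(strata)
    return values[keep], strata[keep]


def factor_q(values: np.ndarray, strata: np.ndarray) -> QResult:
    """Explanatory power of one categorical stratification on the values."""
    v, s = _clean(values, strata)
    if v.size < 2:
        raise ValueError("factor_q needs at least 2 finite observations")
    labels, codes = np.unique(s, return_inverse=True)
    n_h = np.bincount(codes)
    usable = n_h >= 2
    n_excl_strata = int(np.sum(~usable))
    n_excl_values = int(np.sum(n_h[~usable]))
    keep = usable[codes]
    v_u, codes_u = v[keep], codes[keep]
    if usable.sum() < 1:
        raise ValueError("no stratum has at least 2 observations")
    # per-stratum sums for within-stratum sum of squares
    order = np.argsort(codes_u, kind="stable")
    v_u, codes_u = v_u[order], codes_u[order]
    uniq, start = np.unique(codes_u, return_index=True)
    groups = np.split(v_u, start[1:])
    rows, ssw = [], 0.0
    for lab_idx, g in zip(uniq, groups):
        m = g.mean()
        ss = float(np.sum((g - m) ** 2))
        ssw += ss
        rows.append({"stratum": labels[lab_idx], "n_h": g.size,
                     "mean": m, "var": ss / g.size})
    sst = float(np.sum((v_u - v_u.mean()) ** 2))
    degenerate = False
    if len(uniq) < 2:
        warnings.warn("only one usable stratum; q = 0 by convention")
        q = 0.0
        degenerate = True
    elif sst == 0.0:
        q = 0.0
        degenerate = True
    else:
        q = 1.0 - ssw / sst
    return QResult(q=float(np.clip(q, 0.0, 1.0)), n=int(v_u.size),
                   strata=pd.DataFrame(rows),
                   n_excluded_strata=n_excl_strata,
                   n_excluded_values=n_excl_values,
                   degenerate=degenerate)


def _cross_codes(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    _, ca = np.unique(a, return_inverse=True)
    _, cb = np.unique(b, return_inverse=True)
    return ca * (cb.max() + 1) + cb


def interaction_q(values: np.ndarray, strata_a: np.ndarray,
                  strata_b: np.ndarray) -> QResult:
    """q of the cross-classification of two factors plus its category."""
    v, a = _clean(values, strata_a)
    _, b = _clean(values, strata_b)
    if a.shape != b.shape:
        raise ValueError("strata vectors must align with the values")
    cross = _cross_codes(a, b)
    _, counts = np.unique(cross, return_counts=True)
    if (counts >= 2).sum() == 0:
        raise ValueError("all cross-strata are singletons; interaction undefined")
    q_a = factor_q(v, a)
    q_b = factor_q(v, b)
    q_ab = factor_q(v, cross)
    lo, hi = sorted([q_a.q, q_b.q])
    s = q_a.q + q_b.q
    if q_ab.q < lo - _EQ_TOL:
        cat = "nonlinear weaken"
    elif q_ab.q <= hi + _EQ_TOL:
        cat = "univariate weaken"
    elif abs(q_ab.q - s) <= _EQ_TOL:
        cat = "independent"
    elif q_ab.q > s + _EQ_TOL:
        cat = "nonlinear enhance"
    else:
        cat = "bivariate enhance"
    return QResult(q=q_ab.q, n=q_ab.n, strata=q_ab.strata,
                   n_excluded_strata=q_ab.n_excluded_strata,
                   n_excluded_values=q_ab.n_excluded_values,
                   q_a=q_a.q, q_b=q_b.q, interaction=cat,
                   degenerate=q_a.degenerate or q_b.degenerate)


def discretize_continuous(values: np.ndarray, k: int,
                          method: str = "quantile") -> np.ndarray:
    """Bin a continuous covariate into k categories (labels 0..k-1).

    ``quantile`` produces (near-)equal-count classes; ``equal_interval``
    splits the value range evenly.  Empty classes are merged away (labels
    are re-packed) with a warning.  NaN values map to -1.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if method not in {"quantile", "equal_interval"}:
        raise ValueError(f"unknown discretization method {method!r}")
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, -1, dtype=int)
    finite = np.isfinite(v)
    vf = v[finite]
    if vf.size == 0:
        raise ValueError("no finite values to discretize")
    if np.all(vf == vf[0]):
        warnings.warn("constant input: a single class is produced")
        out[finite] = 0
        return out
    if method == "quantile":
        edges = np.quantile(vf, np.linspace(0, 1, k + 1)[1:-1])
        codes = np.searchsorted(edges, vf, side="right")
    else:
        edges = np.linspace(vf.min(), vf.max(), k + 1)[1:-1]
        codes = np.searchsorted(edges, vf, side="right")
    present = np.unique(codes)
    if present.size < k:
        warnings.warn(f"{k - present.size} empty class(es) merged away")
    remap = {c: i for i, c in enumerate(present)}
    out[finite] = np.vectorize(remap.get)(codes)
    return out
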