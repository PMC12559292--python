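"""Vegetation indices for the two emulated sensor band layouts.

Sentinel-2A-like stacks carry six bands resampled to 10 m: b2 (blue), b3
(green), b4 (red), b5 (red edge 1), b8 (NIR), b8A (narrow NIR).  Landsat-8
OLI-like stacks carry three bands at 30 m: b3 (green), b4 (red), b5 (NIR).

Index formulas follow the standard published definitions.  For the Landsat
layout, SAVI uses the NIR/red pair (b5, b4); EVI uses the two-band EVI2 form
because the 3-band layout carries no blue band.  The SAVI soil-adjustment
factor defaults to L = 0.5 and is configurable per call.

Pixels where a formula's denominator vanishes are masked in the output, not
propagated as infinities; the output nodata mask is the union of the input
mask and those degenerate pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .raster import Raster, RasterStack

__all__ = [
    "VIDefinition", "SENSOR_BANDS", "VI_REGISTRY", "available_indices",
    "get_definition", "compute_vi", "extract_at_points",
]

SENSOR_BANDS: dict[str, list[str]] = {
    "s2a": ["b2", "b3", "b4", "b5", "b8", "b8A"],
    "l8": ["b3", "b4", "b5"],
}

_DEGENERATE_EPS = 1e-12


@dataclass(frozen=True)
class VIDefinition:
    """One vegetation index for one sensor layout."""

    name: str
    sensor: str
    required_bands: tuple[str, ...]
    formula: str
    soil_factor_L: float | None = None

    def evaluate(self, bands: dict[str, np.ndarray],
                 L: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, degenerate_mask)."""
        func = _FORMULAE[(self.name, self.sensor)]
        if self.soil_factor_L is not None:
            return func(bands, self.soil_factor_L if L is None else L)
        return func(bands)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    bad = ~np.isfinite(den) | (np.abs(den) < _DEGENERATE_EPS) | ~np.isfinite(num)
    out = np.zeros_like(num, dtype=float)
    np.divide(num, den, out=out, where=~bad)
    return out, bad


def _norm_diff(a, b):
    return _safe_ratio(a - b, a + b)


def _savi(nir, red, L):
    return _safe_ratio((nir - red) * (1.0 + L), nir + red + L)


def _arvi(nir, red, blue):
    rb = 2.0 * red - blue
    return _safe_ratio(nir - rb, nir + rb)


def _rdvi(nir, red):
    s = nir + red
    bad = ~np.isfinite(s) | (s < _DEGENERATE_EPS)
    out = np.zeros_like(nir, dtype=float)
    np.divide(nir - red, np.sqrt(np.where(bad, 1.0, s)), out=out, where=~bad)
    return out, bad


def _evi(nir, red, blue):
    return _safe_ratio(2.5 * (nir - red), nir + 6.0 * red - 7.5 * blue + 1.0)


def _evi2(nir, red):
    return _safe_ratio(2.5 * (nir - red), nir + 2.4 * red + 1.0)


def _gci(nir, green):
    v, bad = _safe_ratio(nir, green)
    return v - 1.0, bad


_FORMULAE: dict[tuple[str, str], Callable] = {
    ("NDVI", "s2a"): lambda b: _norm_diff(b["b8"], b["b4"]),
    ("SAVI", "s2a"): lambda b, L: _savi(b["b8"], b["b4"], L),
    ("gNDVI", "s2a"): lambda b: _norm_diff(b["b8"], b["b3"]),
    ("DVI", "s2a"): lambda b: (b["b8"] - b["b4"], np.zeros(b["b8"].shape, bool)),
    ("reNDVI", "s2a"): lambda b: _norm_diff(b["b8A"], b["b5"]),
    ("SR", "s2a"): lambda b: _safe_ratio(b["b8"], b["b4"]),
    ("reSR", "s2a"): lambda b: _safe_ratio(b["b8A"], b["b5"]),
    ("ARVI", "s2a"): lambda b: _arvi(b["b8"], b["b4"], b["b2"]),
    ("RDVI", "s2a"): lambda b: _rdvi(b["b8"], b["b4"]),
    ("NDWI", "s2a"): lambda b: _norm_diff(b["b3"], b["b8"]),
    ("EVI", "s2a"): lambda b: _evi(b["b8"], b["b4"], b["b2"]),
    ("gCI", "s2a"): lambda b: _gci(b["b8"], b["b3"]),
    ("NDVI", "l8"): lambda b: _norm_diff(b["b5"], b["b4"]),
    ("gNDVI", "l8"): lambda b: _norm_diff(b["b5"], b["b3"]),
    ("SAVI", "l8"): lambda b, L: _savi(b["b5"], b["b4"], L),
    ("DVI", "l8"): lambda b: (b["b5"] - b["b4"], np.zeros(b["b5"].shape, bool)),
    ("SR", "l8"): lambda b: _safe_ratio(b["b5"], b["b4"]),
    ("RDVI", "l8"): lambda b: _rdvi(b["b5"], b["b4"]),
    ("NDWI", "l8"): lambda b: _norm_diff(b["b3"], b["b5"]),
    ("EVI", "l8"): lambda b: _evi2(b["b5"], b["b4"]),
    ("gCI", "l8"): lambda b: _gci(b["b5"], b["b3"]),
}

_BAND_REQUIREMENTS: dict[tuple[str, str], tuple[str, ...]] = {
    ("NDVI", "s2a"): ("b8", "b4"), ("SAVI", "s2a"): ("b8", "b4"),
    ("gNDVI", "s2a"): ("b8", "b3"), ("DVI", "s2a"): ("b8", "b4"),
    ("reNDVI", "s2a"): ("b8A", "b5"), ("SR", "s2a"): ("b8", "b4"),
    ("reSR", "s2a"): ("b8A", "b5"), ("ARVI", "s2a"): ("b8", "b4", "b2"),
    ("RDVI", "s2a"): ("b8", "b4"), ("NDWI", "s2a"): ("b3", "b8"),
    ("EVI", "s2a"): ("b8", "b4", "b2"), ("gCI", "s2a"): ("b8", "b3"),
    ("NDVI", "l8"): ("b5", "b4"), ("gNDVI", "l8"): ("b5", "b3"),
    ("SAVI", "l8"): ("b5", "b4"), ("DVI", "l8"): ("b5", "b4"),
    ("SR", "l8"): ("b5", "b4"), ("RDVI", "l8"): ("b5", "b4"),
    ("NDWI", "l8"): ("b3", "b5"), ("EVI", "l8"): ("b5", "b4"),
    ("gCI", "l8"): ("b5", "b3"),
}

_FORMULA_TEXT: dict[tuple[str, str], str] = {
    ("NDVI", "s2a"): "(b8-b4)/(b8+b4)",
    ("SAVI", "s2a"): "(b8-b4)*(1+L)/(b8+b4+L)",
    ("gNDVI", "s2a"): "(b8-b3)/(b8+b3)",
    ("DVI", "s2a"): "b8-b4",
    ("reNDVI", "s2a"): "(b8A-b5)/(b8A+b5)",
    ("SR", "s2a"): "b8/b4",
    ("reSR", "s2a"): "b8A/b5",
    ("ARVI", "s2a"): "(b8-(2*b4-b2))/(b8+(2*b4-b2))",
    ("RDVI", "s2a"): "(b8-b4)/sqrt(b8+b4)",
    ("NDWI", "s2a"): "(b3-b8)/(b3+b8)",
    ("EVI", "s2a"): "2.5*(b8-b4)/(b8+6*b4-7.5*b2+1)",
    ("gCI", "s2a"): "b8/b3-1",
    ("NDVI", "l8"): "(b5-b4)/(b5+b4)",
    ("gNDVI", "l8"): "(b5-b3)/(b5+b3)",
    ("SAVI", "l8"): "(b5-b4)*(1+L)/(b5+b4+L)",
    ("DVI", "l8"): "b5-b4",
    ("SR", "l8"): "b5/b4",
    ("RDVI", "l8"): "(b5-b4)/sqrt(b5+b4)",
    ("NDWI", "l8"): "(b3-b5)/(b3+b5)",
    ("EVI", "l8"): "2.5*(b5-b4)/(b5+2.4*b4+1)",
    ("gCI", "l8"): "b5/b3-1",
}

VI_REGISTRY: dict[tuple[str, str], VIDefinition] = {
    key: VIDefinition(
        name=key[0], sensor=key[1], required_bands=_BAND_REQUIREMENTS[key],
        formula=_FORMULA_TEXT[key],
        soil_factor_L=0.5 if key[0] == "SAVI" else None)
    for key in _FORMULAE
}


def available_indices(sensor: str) -> list[str]:
    return sorted(name for name, s in VI_REGISTRY if s == sensor)


def get_definition(name: str, sensor: str) -> VIDefinition:
    try:
        return VI_REGISTRY[(name, sensor)]
    except KeyError:
        raise KeyError(
            f"no index {name!r} registered for sensor {sensor!r}; "
            f"available: {available_indices(sensor)}") from None


def compute_vi(stack: RasterStack, definition: VIDefinition | str,
               sensor: str | None = None, L: float | None = None) -> Raster:
    """Evaluate a vegetation index over a band stack.

    ``definition`` may be a :class:`VIDefinition` or an index name, in which
    case ``sensor`` selects the band layout.  Returns a single-band
    :class:`Raster` whose mask is the input mask plus any zero-denominator
    pixels.
    """
    if isinstance(definition, str):
        if sensor is None:
            raise ValueError("sensor layout required when passing an index name")
        definition = get_definition(definition, sensor)
    for b in definition.required_bands:
        if b not in stack.bands:
            raise KeyError(
                f"index {definition.name} requires band {b!r} which is missing "
                f"from the stack (bands: {stack.band_names})")
    values, degenerate = definition.evaluate(stack.bands, L=L)
    mask = stack.nodata_mask | degenerate
    return Raster(values, stack.grid, stack.crs, mask)


def extract_at_points(raster: Raster, points: Sequence[tuple[float, float]]
                      ) -> np.ndarray:
    """Containing-pixel values at the given (x, y) points.

    Masked pixels yield NaN.  A point outside the raster extent raises an
    IndexError naming the offending point index.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    row, col = raster.grid.xy_to_rowcol(pts[:, 0], pts[:, 1])
    rows, cols = raster.shape
    bad = (row < 0) | (row >= rows) | (col < 0) | (col >= cols)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise IndexError(
            f"point {i} at {tuple(pts[i])} falls outside the raster extent")
    values = raster.data[row, col].astype(float)
    values[raster.mask[row, col]] = np.nan
    return values
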