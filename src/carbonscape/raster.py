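"""Lightweight georeferenced raster containers and plain-text grid I/O.

All grids in this package are north-up, single-CRS, pixel-is-area rasters.
A pixel (row, col) covers the half-open square
``[origin_x + col*px, origin_x + (col+1)*px) x (origin_y - (row+1)*px, origin_y - row*px]``
with the grid origin at the top-left (north-west) corner.  Point lookups are
containment based — no interpolation anywhere in the package.

Files are read and written as ESRI ASCII grids (``.asc``), a plain-text
raster format understood by GDAL, QGIS and ArcGIS.  Continuous rasters use
nodata -9999; categorical rasters use nodata 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NODATA_CONTINUOUS = -9999.0
NODATA_CATEGORICAL = 0


@dataclass(frozen=True)
class GridSpec:
    """North-up affine georeference: top-left corner and square pixel size (m)."""

    origin_x: float
    origin_y: float
    pixel_size: float

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing pixel of each point (floor on the half-open pixel square)."""
        col = np.floor((np.asarray(x, float) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y, float)) / self.pixel_size)
        return row.astype(int), col.astype(int)

    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates of the given pixels."""
        x = self.origin_x + (np.asarray(col, float) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row, float) + 0.5) * self.pixel_size
        return x, y

    def coarsen(self, factor: int) -> "GridSpec":
        return GridSpec(self.origin_x, self.origin_y, self.pixel_size * factor)


@dataclass
class Raster:
    """A single-band raster: 2-D float or integer grid plus georeference.

    ``mask`` is True where the pixel is nodata.
    """

    data: np.ndarray
    grid: GridSpec
    crs: str = "local"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape does not match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def resolution_m(self) -> float:
        return self.grid.pixel_size

    def valid_values(self) -> np.ndarray:
        return self.data[~self.mask]

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.grid, self.crs, self.mask.copy())

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "Raster":
        """Sub-window [row0:row1, col0:col1] with a shifted origin."""
        g = GridSpec(
            self.grid.origin_x + col0 * self.grid.pixel_size,
            self.grid.origin_y - row0 * self.grid.pixel_size,
            self.grid.pixel_size,
        )
        return Raster(self.data[row0:row1, col0:col1].copy(), g, self.crs,
                      self.mask[row0:row1, col0:col1].copy())


@dataclass
class RasterStack:
    """A co-registered multiband reflectance stack with a named-band map."""

    bands: dict[str, np.ndarray]
    grid: GridSpec
    crs: str = "local"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        shapes = {b: np.asarray(a).shape for b, a in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"bands have inconsistent shapes: {shapes}")
        self.bands = {b: np.asarray(a, dtype=float) for b, a in self.bands.items()}
        shape = next(iter(shapes.values()))
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != shape:
                raise ValueError("nodata mask shape does not match band shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    @property
    def resolution_m(self) -> float:
        return self.grid.pixel_size

    def band(self, name: str) -> np.ndarray:
        if name not in self.bands:
            raise KeyError(
                f"band {name!r} not present in stack (available: {sorted(self.bands)})")
        return self.bands[name]

    def crop(self, row0: int, row1: int, col0: int, col1: int) -> "RasterStack":
        g = GridSpec(
            self.grid.origin_x + col0 * self.grid.pixel_size,
            self.grid.origin_y - row0 * self.grid.pixel_size,
            self.grid.pixel_size,
        )
        return RasterStack(
            {b: a[row0:row1, col0:col1].copy() for b, a in self.bands.items()},
            g, self.crs, self.nodata_mask[row0:row1, col0:col1].copy())


def block_reduce_mean(a: np.ndarray, factor: int) -> np.ndarray:
    """Mean over non-overlapping factor x factor blocks (shape must divide)."""
    r, c = a.shape
    if r % factor or c % factor:
        raise ValueError(f"shape {a.shape} not divisible by block factor {factor}")
    return a.reshape(r // factor, factor, c // factor, factor).mean(axis=(1, 3))


def grids_nested(fine: GridSpec, coarse: GridSpec, factor: int = 3,
                 tol: float = 1e-6) -> bool:
    """True when the fine grid exactly nests inside the coarse grid (shared origin)."""
    return (
        abs(fine.origin_x - coarse.origin_x) < tol
        and abs(fine.origin_y - coarse.origin_y) < tol
        and abs(fine.pixel_size * factor - coarse.pixel_size) < tol
    )


def write_ascii_grid(path: str | Path, raster: Raster,
                     nodata: float | int | None = None,
                     fmt: str = "%.8g") -> None:
    if nodata is None:
        nodata = (NODATA_CATEGORICAL if np.issubdtype(raster.data.dtype, np.integer)
                  else NODATA_CONTINUOUS)
    rows, cols = raster.shape
    g = raster.grid
    out = np.where(raster.mask, nodata, raster.data)
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y - rows * g.pixel_size!r}\n"
        f"cellsize {g.pixel_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path, dtype=float, crs: str = "local") -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                    "nodata_value"}:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float)
    rows, cols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(rows, cols)
    nodata = header.get("nodata_value")
    mask = np.zeros(data.shape, bool) if nodata is None else np.isclose(data, nodata)
    grid = GridSpec(header["xllcorner"],
                    header["yllcorner"] + rows * header["cellsize"],
                    header["cellsize"])
    return Raster(data.astype(dtype), grid, crs, mask)
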