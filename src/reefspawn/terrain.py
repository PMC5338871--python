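"""Bathymetric terrain derivatives.

Depth rasters (metres, positive down) are turned into the covariates used to
characterise spawning habitat: bathymetric position index (BPI) at a broad and
a fine annulus, slope, aspect and curvature, each summarised (mean and max)
inside circular buffers around sampling points.

Conventions
-----------
* Grids are regular, projected in metres, stored with row 0 at the north edge;
  ``origin`` is the lower-left corner (Esri ASCII convention).
* Elevation is the negative of depth; BPI > 0 is a ridge, < 0 a valley.
* Slope/aspect use Horn's 3x3 weighted finite differences; curvature is the
  general curvature of the 3x3 quadratic surface fit (Zevenbergen-Thorne),
  reported in 1/100 m with positive = convex.
* Aspect is degrees clockwise from north; perfectly flat cells are nodata and
  buffer means of aspect are circular (vector) means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

EARTH_RADIUS_M = 6_371_008.8
#: metres per degree of latitude (spherical earth)
M_PER_DEG = EARTH_RADIUS_M * math.pi / 180.0

BROAD_BUFFER_M = 381.8   # hypotenuse of a 3x3 block of 90 m cells
FINE_BUFFER_M = 127.0    # hypotenuse of a 3x3 block of 30 m cells


@dataclass
class BathymetryGrid:
    """Regular raster of seafloor depth (metres, positive down).

    ``lat0``/``lon0`` optionally georeference the projected origin so grid
    coordinates can be exchanged with geographic ones (equirectangular about
    ``lat0``; adequate at the survey scales handled here).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    lat0: float | None = None
    lon0: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("bathymetry must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.mask
        if np.any(self.values[valid] < 0):
            raise ValueError("depths must be non-negative (positive down)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, finite) cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    @property
    def elevation(self) -> np.ndarray:
        """Elevation (= -depth) with nodata as NaN."""
        e = -self.values.astype(float)
        e[~self.mask] = np.nan
        return e

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centers, row-major."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (nrows - np.arange(nrows) - 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of points; -1 where outside the raster."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        nrows, ncols = self.shape
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = (nrows - 1 - np.floor((y - self.origin[1]) / self.cell_size)).astype(int)
        bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
        row[bad] = -1
        col[bad] = -1
        return row, col

    def depth_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.index_of(x, y)
        out = np.full(row.shape, np.nan)
        ok = row >= 0
        vals = self.values[row[ok], col[ok]]
        vals = np.where(vals == self.nodata, np.nan, vals)
        out[ok] = vals
        return out

    # -- geographic exchange -------------------------------------------------
    def xy_to_lonlat(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.lat0 is None or self.lon0 is None:
            raise ValueError("grid has no geographic reference (lat0/lon0)")
        lat = self.lat0 + np.asarray(y) / M_PER_DEG
        lon = self.lon0 + np.asarray(x) / (M_PER_DEG * math.cos(math.radians(self.lat0)))
        return lon, lat

    def lonlat_to_xy(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.lat0 is None or self.lon0 is None:
            raise ValueError("grid has no geographic reference (lat0/lon0)")
        y = (np.asarray(lat) - self.lat0) * M_PER_DEG
        x = (np.asarray(lon) - self.lon0) * M_PER_DEG * math.cos(math.radians(self.lat0))
        return x, y


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O (plain-text raster interchange format)
# ---------------------------------------------------------------------------

def read_ascii_grid(path) -> BathymetryGrid:
    """Read an Esri ASCII grid of depths."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array([v for row in rows for v in row], dtype=float)
    values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return BathymetryGrid(
        values=values,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: BathymetryGrid, path) -> None:
    nrows, ncols = grid.shape
    vals = np.where(grid.mask, grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"nodata_value {grid.nodata:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Terrain derivatives
# ---------------------------------------------------------------------------

def _annulus_footprint(inner_cells: float, outer_cells: float) -> np.ndarray:
    """Boolean footprint of cells with center distance d (cell units)
    satisfying inner < d <= outer."""
    r = int(math.ceil(outer_cells))
    di, dj = np.mgrid[-r:r + 1, -r:r + 1]
    d = np.hypot(di, dj)
    return (d > inner_cells) & (d <= outer_cells)


def compute_bpi(grid: BathymetryGrid, inner_cells: float, outer_cells: float) -> np.ndarray:
    """Bathymetric position index: elevation minus mean elevation in an
    annulus of inner/outer radius given in cell units.

    Nodata-aware: annulus means use valid neighbours only; cells whose own
    value is nodata, or with an empty valid annulus, are NaN.
    """
    if not 0 <= inner_cells < outer_cells:
        raise ValueError("require 0 <= inner_cells < outer_cells")
    fp = _annulus_footprint(inner_cells, outer_cells)
    if not fp.any():
        raise ValueError("annulus footprint is empty")
    elev = grid.elevation
    valid = np.isfinite(elev).astype(float)
    filled = np.where(valid > 0, elev, 0.0)
    ssum = ndimage.correlate(filled, fp.astype(float), mode="constant", cval=0.0)
    cnt = ndimage.correlate(valid, fp.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bpi = elev - ssum / cnt
    bpi[cnt == 0] = np.nan
    return bpi


def compute_slope_aspect_curvature(
    grid: BathymetryGrid,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope (deg), aspect (deg CW from north, NaN when flat) and general
    curvature (1/100 m, positive convex) on the elevation surface.

    Border cells (and any 3x3 neighbourhood touching nodata) are NaN.
    """
    if grid.shape[0] < 3 or grid.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    z = grid.elevation
    h = grid.cell_size

    # 3x3 neighbourhood, letters laid out a b c / d e f / g h i, row 0 = north
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2]; e = z[1:-1, 1:-1]; f = z[1:-1, 2:]
    g = z[2:, :-2]; hh = z[2:, 1:-1]; i = z[2:, 2:]

    with np.errstate(invalid="ignore"):
        dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * h)   # east
        dzdy = ((a + 2 * b + c) - (g + 2 * hh + i)) / (8 * h)  # north
        slope_in = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
        # downslope azimuth, clockwise from north
        aspect_in = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
        flat = np.isclose(dzdx, 0.0) & np.isclose(dzdy, 0.0)
        aspect_in = np.where(flat, np.nan, aspect_in)
        # Zevenbergen-Thorne quadratic fit; ESRI reports -200*(D+E)
        D = ((d + f) / 2 - e) / h**2
        E = ((b + hh) / 2 - e) / h**2
        curv_in = -2.0 * (D + E) * 100.0

    def pad(arr):
        out = np.full(grid.shape, np.nan)
        out[1:-1, 1:-1] = arr
        return out

    return pad(slope_in), pad(aspect_in), pad(curv_in)


@dataclass
class TerrainStack:
    """Aligned terrain-derivative rasters sharing the source grid geometry."""

    grid: BathymetryGrid
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    #: layers whose buffer mean must be circular
    CIRCULAR = ("aspect",)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    @property
    def names(self) -> list[str]:
        return list(self.layers)


def compute_terrain(
    grid: BathymetryGrid,
    broad_outer: int = 18,
    fine_outer: int = 9,
    inner: int = 1,
    round_bpi: bool = False,
) -> TerrainStack:
    """Full derivative stack: slope, aspect, curvature, broad/fine BPI.

    ``round_bpi`` rounds BPI to integers for parity with desktop GIS tools
    that quantize; kept off by default.
    """
    slope, aspect, curv = compute_slope_aspect_curvature(grid)
    bpi_broad = compute_bpi(grid, inner, broad_outer)
    bpi_fine = compute_bpi(grid, inner, fine_outer)
    if round_bpi:
        bpi_broad = np.round(bpi_broad)
        bpi_fine = np.round(bpi_fine)
    return TerrainStack(
        grid=grid,
        layers={
            "slope": slope,
            "aspect": aspect,
            "curvature": curv,
            "bpi_broad": bpi_broad,
            "bpi_fine": bpi_fine,
        },
    )


def _circular_mean_deg(angles: np.ndarray) -> float:
    rad = np.radians(angles)
    s, c = np.nanmean(np.sin(rad)), np.nanmean(np.cos(rad))
    if np.hypot(s, c) < 1e-12:
        return np.nan
    return float(np.degrees(np.arctan2(s, c)) % 360.0)


def summarize_buffer(
    stack: TerrainStack,
    points: pd.DataFrame | np.ndarray,
    radius: float = BROAD_BUFFER_M,
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Mean and max of each terrain layer within ``radius`` metres of each
    point (grid coordinates).

    ``points`` is an (n, 2) array of (x, y) or a DataFrame with columns
    ``x``/``y``; the result is indexed like the input and has columns
    ``mean_<layer>``, ``max_<layer>``, ``n_cells`` and ``missing``. Points
    outside the raster, or covering no valid cell, are flagged missing (NaN
    statistics), not an error.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(float)
        index = points.index
    else:
        xy = np.atleast_2d(np.asarray(points, dtype=float))
        index = pd.RangeIndex(len(xy))
    grid = stack.grid
    names = layers if layers is not None else stack.names
    nrows, ncols = grid.shape
    xs, ys = grid.cell_centers()
    r_cells = int(math.ceil(radius / grid.cell_size))

    records = []
    for x, y in xy:
        col_c = int(np.floor((x - grid.origin[0]) / grid.cell_size))
        row_c = int(nrows - 1 - np.floor((y - grid.origin[1]) / grid.cell_size))
        r0, r1 = max(row_c - r_cells, 0), min(row_c + r_cells + 1, nrows)
        c0, c1 = max(col_c - r_cells, 0), min(col_c + r_cells + 1, ncols)
        rec: dict[str, float] = {}
        if r0 >= r1 or c0 >= c1:
            for name in names:
                rec[f"mean_{name}"] = np.nan
                rec[f"max_{name}"] = np.nan
            rec["n_cells"] = 0
            rec["missing"] = True
            records.append(rec)
            continue
        dx = xs[c0:c1][None, :] - x
        dy = ys[r0:r1][:, None] - y
        inside = np.hypot(dx, dy) <= radius
        n_any = 0
        for name in names:
            vals = stack[name][r0:r1, c0:c1][inside]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                rec[f"mean_{name}"] = np.nan
                rec[f"max_{name}"] = np.nan
                continue
            n_any = max(n_any, vals.size)
            if name in stack.CIRCULAR:
                rec[f"mean_{name}"] = _circular_mean_deg(vals)
            else:
                rec[f"mean_{name}"] = float(vals.mean())
            rec[f"max_{name}"] = float(vals.max())
        rec["n_cells"] = int(inside.sum())
        rec["missing"] = n_any == 0
        records.append(rec)
    out = pd.DataFrame(records, index=index)
    if out["missing"].any():
        warnings.warn(
            f"{int(out['missing'].sum())} point(s) covered no valid raster cells",
            stacklevel=2,
        )
    return out


def moving_buffer_stats(
    stack: TerrainStack, layer: str, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell circular-buffer (mean, max) rasters for one layer.

    Used to attach buffer-summarised covariates to every cell of a
    prediction grid; equivalent to :func:`summarize_buffer` evaluated at each
    cell center (plain mean also for aspect here — gridded aspect covariates
    are binned downstream, where the distinction is immaterial).
    """
    r_cells = int(math.ceil(radius / stack.grid.cell_size))
    di, dj = np.mgrid[-r_cells:r_cells + 1, -r_cells:r_cells + 1]
    fp = np.hypot(di, dj) * stack.grid.cell_size <= radius
    vals = stack[layer]
    valid = np.isfinite(vals).astype(float)
    filled = np.where(valid > 0, vals, 0.0)
    ssum = ndimage.correlate(filled, fp.astype(float), mode="constant", cval=0.0)
    cnt = ndimage.correlate(valid, fp.astype(float), mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = ssum / cnt
    mean[cnt == 0] = np.nan
    filled_min = np.where(valid > 0, vals, -np.inf)
    mx = ndimage.maximum_filter(filled_min, footprint=fp, mode="constant", cval=-np.inf)
    mx = np.where(np.isfinite(mx), mx, np.nan)
    mx[cnt == 0] = np.nan
    return mean, mx
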