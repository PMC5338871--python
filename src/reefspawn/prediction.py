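"""Peak-spawning prediction maps and external validation.

Given a fitted spawning model, builds a coarser prediction grid (block
aggregation of the terrain rasters, mirroring the 90 m -> 270 m statistics
grid), fixes the temporal covariates (month, temperature, lunar phase) at
their peak values, predicts the probability of encountering a spawning
condition female per cell with a delta-method standard error, standardises
the probability surface to Z-scores, and scores independent validation
points: a point over a cell with Z > 0 supports the prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import DesignMatrix, encode_new
from .glmm import ModelFit, predict_with_se
from .terrain import (
    BROAD_BUFFER_M,
    BathymetryGrid,
    TerrainStack,
    moving_buffer_stats,
)


def _block_reduce(arr: np.ndarray, block: int, how: str = "mean") -> np.ndarray:
    """Aggregate an array over non-overlapping block x block windows
    (NaN-aware); trailing partial rows/cols are dropped."""
    nr = (arr.shape[0] // block) * block
    nc = (arr.shape[1] // block) * block
    a = arr[:nr, :nc].reshape(nr // block, block, nc // block, block)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if how == "mean":
            return np.nanmean(a, axis=(1, 3))
        if how == "max":
            return np.nanmax(a, axis=(1, 3))
    raise ValueError(how)


@dataclass
class GridCovariates:
    """Flattened design-ready rows for the valid cells of a prediction grid."""

    table: pd.DataFrame          # one row per valid cell
    rows: np.ndarray             # cell row index into the block grid
    cols: np.ndarray
    shape: tuple[int, int]
    cell_size: float
    origin: tuple[float, float]
    grid: BathymetryGrid


def build_grid_covariates(
    bathy: BathymetryGrid,
    stack: TerrainStack,
    design: DesignMatrix,
    block: int = 3,
    max_depth: float = 200.0,
    buffer_radius: float = BROAD_BUFFER_M,
) -> GridCovariates:
    """Cell covariates for the prediction grid.

    Terrain buffer statistics (``mean_*`` / ``max_*`` of each layer used by
    the fitted model) are computed per source cell with a moving circular
    buffer, then block-aggregated (mean) to the coarser grid; depth and
    latitude come from block means. Cells deeper than ``max_depth`` or on
    land are dropped (nodata).
    """
    needed = [
        m["source"]
        for t, m in design.meta.items()
        if m["kind"] != "interaction" and m["source"].startswith(("mean_", "max_"))
    ]
    layer_stats: dict[str, np.ndarray] = {}
    for src in dict.fromkeys(needed):
        stat, layer = src.split("_", 1)
        mean_r, max_r = moving_buffer_stats(stack, layer, buffer_radius)
        layer_stats[src] = mean_r if stat == "mean" else max_r

    depth = np.where(bathy.mask, bathy.values, np.nan)
    depth_b = _block_reduce(depth, block, "mean")
    shape = depth_b.shape
    cell = bathy.cell_size * block
    nrows_b, ncols_b = shape
    x0, y0 = bathy.origin
    # block grid shares the source origin; row 0 stays the north edge
    top = y0 + bathy.shape[0] * bathy.cell_size
    xs = x0 + (np.arange(ncols_b) + 0.5) * cell
    ys = top - (np.arange(nrows_b) + 0.5) * cell
    xg, yg = np.meshgrid(xs, ys)
    if bathy.lat0 is not None:
        lon_g, lat_g = bathy.xy_to_lonlat(xg, yg)
    else:
        lon_g, lat_g = xg, yg

    cols = {"depth_m": depth_b.ravel(), "lat": np.asarray(lat_g).ravel(),
            "lon": np.asarray(lon_g).ravel(), "x": xg.ravel(), "y": yg.ravel()}
    for src, raster in layer_stats.items():
        cols[src] = _block_reduce(raster, block, "mean").ravel()
    table = pd.DataFrame(cols)
    valid = (
        table["depth_m"].notna()
        & (table["depth_m"] > 0)
        & (table["depth_m"] <= max_depth)
    )
    for src in layer_stats:
        valid &= table[src].notna()
    idx = np.where(valid.to_numpy())[0]
    rr, cc = np.unravel_index(idx, shape)
    return GridCovariates(
        table=table.loc[idx].reset_index(drop=True),
        rows=rr,
        cols=cc,
        shape=shape,
        cell_size=cell,
        origin=(x0, y0),
        grid=bathy,
    )


@dataclass
class PredictionGrid:
    probability: np.ndarray
    se: np.ndarray
    z: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    peak_settings: dict = field(default_factory=dict)
    grid: BathymetryGrid | None = None

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nrows, ncols = self.probability.shape
        if self.grid is not None:
            top = self.grid.origin[1] + self.grid.shape[0] * self.grid.cell_size
        else:
            top = self.origin[1] + nrows * self.cell_size
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((top - np.asarray(y)) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= ncols) | (row < 0) | (row >= nrows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col


def peak_settings(fit: ModelFit, design: DesignMatrix, terms=("month", "temp_c", "lunar3", "lunar_bin", "lunar_cat")) -> dict:
    """Peak value per temporal term: the factor level (or continuous value,
    over its observed range) maximising the fitted linear predictor."""
    out: dict[str, object] = {}
    coef = fit.params
    for term in design.terms:
        if term not in terms or term not in design.meta:
            continue
        m = design.meta[term]
        if m["kind"] == "continuous":
            lo, hi = m.get("range", (-1.0, 1.0))
            b = coef.get(term, 0.0)
            out[m["source"]] = hi if b >= 0 else lo
        else:
            levels = m["levels"]
            contribs = {
                lev: float(coef.get(f"{term}[{lev}]", 0.0)) for lev in levels
            }
            best = max(levels, key=lambda lev: contribs[lev])
            out[m["source"]] = best
    return out


def predict_map(
    fit: ModelFit,
    grid_cov: GridCovariates,
    design: DesignMatrix | None = None,
    peak: dict | None = None,
) -> PredictionGrid:
    """Probability, standard-error and Z-score rasters at peak conditions.

    ``peak`` overrides the auto-selected peak settings (keys are source
    column names, e.g. ``month`` or ``temp_c``).
    """
    design = design if design is not None else fit.design
    if design is None:
        raise ValueError("need the fitted DesignMatrix for encoding metadata")
    settings = peak_settings(fit, design)
    if peak:
        settings.update(peak)
    newdata = grid_cov.table.copy()
    for col, val in settings.items():
        newdata[col] = val
    # any sources the model needs but the grid lacks: hold at reference level
    for t, m in design.meta.items():
        if m["kind"] != "interaction" and m["source"] not in newdata.columns:
            filler = m.get("reference", m["levels"][0]) if "levels" in m else 0.0
            newdata[m["source"]] = filler
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        X = encode_new(design, newdata)
    p, se = predict_with_se(fit, X)
    prob = np.full(grid_cov.shape, np.nan)
    serr = np.full(grid_cov.shape, np.nan)
    prob[grid_cov.rows, grid_cov.cols] = p
    serr[grid_cov.rows, grid_cov.cols] = se
    pg = PredictionGrid(
        probability=prob,
        se=serr,
        z=np.full(grid_cov.shape, np.nan),
        cell_size=grid_cov.cell_size,
        origin=grid_cov.origin,
        peak_settings=settings,
        grid=grid_cov.grid,
    )
    return zscore(pg)


def zscore(grid: PredictionGrid) -> PredictionGrid:
    """Standardise the probability surface over its non-nodata cells
    (population SD)."""
    p = grid.probability
    ok = np.isfinite(p)
    if ok.sum() < 2:
        raise ValueError("need at least 2 valid cells to standardise")
    mu = p[ok].mean()
    sd = p[ok].std()
    z = np.full(p.shape, np.nan)
    if sd == 0:
        warnings.warn("zero variance in probability surface; Z set to 0", stacklevel=2)
        z[ok] = 0.0
    else:
        z[ok] = (p[ok] - mu) / sd
    grid.z = z
    return grid


def external_validation(
    grid: PredictionGrid, points: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score validation points against the Z-surface.

    ``points`` needs ``x``/``y`` (grid CRS) or ``lon``/``lat`` when the grid
    is georeferenced, and optionally a ``source`` label. Returns (per-point
    table with z and support flag, per-source summary incl. overall).
    Points off-grid or over nodata are flagged and excluded from fractions.
    """
    pts = points.copy()
    if "x" not in pts.columns:
        if grid.grid is None:
            raise ValueError("points lack x/y and grid has no georeference")
        x, y = grid.grid.lonlat_to_xy(pts["lon"].to_numpy(), pts["lat"].to_numpy())
        pts["x"], pts["y"] = x, y
    row, col = grid.cell_of(pts["x"].to_numpy(), pts["y"].to_numpy())
    z = np.full(len(pts), np.nan)
    ok = row >= 0
    z[ok] = grid.z[row[ok], col[ok]]
    pts["z_score"] = z
    pts["in_grid"] = np.isfinite(z)
    pts["support"] = np.isfinite(z) & (z > 0)
    if not pts["in_grid"].any():
        warnings.warn("no validation points fall on the grid", stacklevel=2)
    if "source" not in pts.columns:
        pts["source"] = "all"
    rows = []
    groups = list(pts.groupby("source")) + [("overall", pts)]
    for name, grp in groups:
        ing = grp[grp["in_grid"]]
        rows.append(
            {
                "source": name,
                "n_points": len(grp),
                "n_in_grid": len(ing),
                "n_support": int(ing["support"].sum()),
                "support_fraction": float(ing["support"].mean()) if len(ing) else np.nan,
                "median_z": float(ing["z_score"].median()) if len(ing) else np.nan,
            }
        )
    return pts, pd.DataFrame(rows)
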