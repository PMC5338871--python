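"""Synthetic shelf-edge survey generator.

Emulates a fishery-independent reef-fish survey over a shelf-edge bathymetry
so that every downstream stage — terrain covariates, the mixed-effects
spawning model, stepwise selection, cross-validation, the randomization test
and prediction maps — can be exercised against a fully known generative
truth.

The bathymetry is a monotone cross-shelf depth gradient plus one or more
Gaussian ridge features (the "shelf edge") and smooth correlated noise. The
survey places gear sets uniformly over depth-eligible cells, draws a
sampling month weighted toward the May-September field season, derives
bottom temperature from a seasonal/depth model, and draws each examined
female's spawning flag from a Bernoulli whose logit is a linear function of
known covariates plus a year-level random intercept.

What this emulates and what it does not: the generator reproduces the
statistical structure the analysis assumes (set-level covariates shared by
fish within a set, year-to-year intercept heterogeneity, a seasonal peak,
terrain dependence); it makes no attempt to mimic gear selectivity, trap
soak times, or real regional geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import covariates as cov
from .terrain import BROAD_BUFFER_M, BathymetryGrid, TerrainStack, summarize_buffer

#: covariate features the true logit model may reference; each maps a record
#: to a (roughly unit-scale) regressor. Centering constants are part of the
#: generative definition, not tuning knobs.
TRUE_FEATURES = {
    "temp_c": lambda r: r["temp_c"] - 22.0,
    "lat": lambda r: r["lat"] - 32.0,
    "depth_m": lambda r: r["depth_m"] - 40.0,
    "lunar3": lambda r: r["lunar3"],
    "month_peak": lambda r: np.exp(-((r["month"] - 6.5) ** 2) / (2 * 1.5**2)),
    "bpi_broad": lambda r: r["mean_bpi_broad"],
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic survey.

    Defaults describe a mid-shelf survey: a ~9 km square of 90 m cells, ten
    sampling years, a hundred gear sets per year with 1-12 histologically
    examined mature females each (the per-set count distribution is not
    documented for the real survey; the 1-12 uniform range is a declared
    guess), effort concentrated May-September, and a true spawning model
    with a June-July peak, positive temperature and ridge (BPI) effects, a
    waning-moon preference, and year intercepts with SD 0.5 logits.
    """

    grid_rows: int = 96
    grid_cols: int = 96
    cell_size: float = 90.0
    n_years: int = 10
    n_sets_per_year: int = 100
    females_per_set_range: tuple[int, int] = (1, 12)
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -1.2,
            "temp_c": 0.3,
            "month_peak": 1.2,
            "lunar3": -0.5,
            "bpi_broad": 0.2,
        }
    )
    random_intercept_sd: float = 0.5
    #: (surface mean degC, seasonal amplitude degC, depth lapse degC/m, noise sd degC)
    temperature_model: tuple[float, float, float, float] = (26.0, 3.0, 0.06, 1.0)
    month_weights: tuple[float, ...] = (1, 1, 2, 3, 8, 10, 10, 8, 6, 2, 1, 1)
    first_year: int = 2004
    depth_range: tuple[float, float] = (10.0, 200.0)
    ridges: tuple[tuple[float, float, float], ...] = ((0.62, 25.0, 3.0),)
    noise_sd: float = 1.5
    noise_corr_cells: float = 3.0
    lat0: float = 31.6
    lon0: float = -79.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 16 or self.grid_cols < 16:
            raise ValueError("grid must be at least 16x16")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.females_per_set_range[0] < 1:
            raise ValueError("females_per_set_range lower bound must be >= 1")
        unknown = set(self.true_coefficients) - set(TRUE_FEATURES) - {"intercept"}
        if unknown:
            raise ValueError(f"unsupported true-coefficient term(s): {sorted(unknown)}")


@dataclass
class SurveyTable:
    """Generated collections plus the retained truth columns (kept in a
    sidecar frame so the analysis path consumes exactly the public CSV
    schema)."""

    records: pd.DataFrame   # the collections schema
    truth: pd.DataFrame     # record_id, true_logit, true_p, year_intercept
    year_intercepts: pd.Series
    config: SimulationConfig


def generate_bathymetry(config: SimulationConfig) -> BathymetryGrid:
    """Depth raster: cross-shelf gradient (shallow west edge ~10 m to deep
    east edge ~200 m) + Gaussian ridges + smooth correlated noise.
    Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    nrows, ncols = config.grid_rows, config.grid_cols
    d0, d1 = config.depth_range
    xfrac = (np.arange(ncols) + 0.5) / ncols
    depth = d0 + (d1 - d0) * xfrac[None, :] * np.ones((nrows, 1))
    for center_frac, amp, width in config.ridges:
        c = center_frac * ncols
        depth -= amp * np.exp(-((np.arange(ncols) - c) ** 2) / (2 * width**2))[None, :]
    if config.noise_sd > 0:
        white = rng.standard_normal((nrows, ncols))
        smooth = gaussian_filter(white, config.noise_corr_cells, mode="reflect")
        smooth *= config.noise_sd / smooth.std()
        depth = depth + smooth
    depth = np.clip(depth, 1.0, None)
    return BathymetryGrid(
        values=depth,
        cell_size=config.cell_size,
        origin=(0.0, 0.0),
        lat0=config.lat0,
        lon0=config.lon0,
    )


def _true_logit(records: pd.DataFrame, coeffs: dict[str, float]) -> np.ndarray:
    eta = np.full(len(records), coeffs.get("intercept", 0.0), dtype=float)
    for name, c in coeffs.items():
        if name == "intercept":
            continue
        eta += c * np.asarray(TRUE_FEATURES[name](records), dtype=float)
    return eta


def generate_survey(
    config: SimulationConfig,
    bathy: BathymetryGrid,
    terrain: TerrainStack | None = None,
) -> SurveyTable:
    """Draw the survey records from the known generative model.

    ``terrain`` must share the bathymetry geometry; it is only required when
    the true model includes a terrain feature.
    """
    needs_terrain = any(k == "bpi_broad" for k in config.true_coefficients)
    if needs_terrain and terrain is None:
        raise ValueError("true model includes a terrain feature; pass the TerrainStack")
    if terrain is not None and terrain.grid.shape != bathy.shape:
        raise ValueError("terrain stack is not aligned with the bathymetry grid")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    eligible_r, eligible_c = np.where(
        bathy.mask
        & (bathy.values >= config.depth_range[0])
        & (bathy.values <= config.depth_range[1])
    )
    if eligible_r.size == 0:
        raise ValueError("no depth-eligible cells to place sets on")
    xs, ys = bathy.cell_centers()
    mean_t, amp_t, lapse, noise_t = config.temperature_model
    mw = np.asarray(config.month_weights, dtype=float)
    mw = mw / mw.sum()

    n_sets = config.n_years * config.n_sets_per_year
    years = np.repeat(
        np.arange(config.first_year, config.first_year + config.n_years),
        config.n_sets_per_year,
    )
    u = rng.normal(0.0, config.random_intercept_sd, size=config.n_years)
    year_intercepts = pd.Series(
        u, index=np.arange(config.first_year, config.first_year + config.n_years)
    )

    pick = rng.integers(0, eligible_r.size, size=n_sets)
    rr, cc = eligible_r[pick], eligible_c[pick]
    jitter = rng.uniform(-0.5, 0.5, size=(n_sets, 2)) * bathy.cell_size
    x = xs[cc] + jitter[:, 0]
    y = ys[rr] + jitter[:, 1]
    lon, lat = bathy.xy_to_lonlat(x, y)
    depth = bathy.values[rr, cc]
    month = rng.choice(np.arange(1, 13), size=n_sets, p=mw)
    day = rng.integers(1, 29, size=n_sets)
    dates = pd.to_datetime(
        {"year": years, "month": month, "day": day}
    )
    # seasonal bottom temperature, cooling with depth, peak in August
    temp = (
        mean_t
        + amp_t * np.cos(2 * np.pi * (month - 8) / 12)
        - lapse * depth
        + rng.normal(0, noise_t, size=n_sets)
    )
    temp = np.clip(temp, 2.0, None)
    salinity = rng.normal(36.0, 0.3, size=n_sets).round(1)
    gear = rng.choice(["CVT", "SBL"], size=n_sets, p=[0.8, 0.2])
    habitat = rng.choice(["HB", "PH", "NH", "UNK"], size=n_sets, p=[0.5, 0.2, 0.1, 0.2])

    sets = pd.DataFrame(
        {
            "set_id": [f"S{i:05d}" for i in range(n_sets)],
            "date": dates,
            "year": years,
            "month": month,
            "lon": lon,
            "lat": lat,
            "x": x,
            "y": y,
            "gear": gear,
            "depth_m": depth,
            "temp_c": np.round(temp, 2),
            "salinity_ppt": salinity,
            "habitat": habitat,
        }
    )
    lun = cov.lunar3(sets["date"])
    sets["lunar3"] = lun["lunar3"].to_numpy()
    sets["lunar_cat"] = lun["lunar_cat"].to_numpy()

    if terrain is not None:
        buf = summarize_buffer(
            terrain, sets[["x", "y"]], radius=BROAD_BUFFER_M, layers=["bpi_broad"]
        )
        sets["mean_bpi_broad"] = buf["mean_bpi_broad"].to_numpy()
    else:
        sets["mean_bpi_broad"] = 0.0

    lo, hi = config.females_per_set_range
    n_fish = rng.integers(lo, hi + 1, size=n_sets)
    records = sets.loc[np.repeat(sets.index, n_fish)].reset_index(drop=True)
    records["species"] = "SYN"

    eta = _true_logit(records, config.true_coefficients)
    eta = eta + year_intercepts.loc[records["year"]].to_numpy()
    p = expit(eta)
    records["spawning"] = rng.binomial(1, p)

    truth = pd.DataFrame(
        {
            "record_id": np.arange(len(records)),
            "set_id": records["set_id"].to_numpy(),
            "true_logit": eta,
            "true_p": p,
            "year_intercept": year_intercepts.loc[records["year"]].to_numpy(),
        }
    )
    public = records[cov.COLLECTION_COLUMNS + ["x", "y", "lunar3", "lunar_cat"]]
    return SurveyTable(
        records=public.copy(), truth=truth, year_intercepts=year_intercepts,
        config=config,
    )


def write_survey(table: SurveyTable, records_path, truth_path=None) -> None:
    """Write the public collections CSV (exact schema) and, optionally, the
    truth sidecar CSV."""
    table.records[cov.COLLECTION_COLUMNS].to_csv(records_path, index=False)
    if truth_path is not None:
        table.truth.to_csv(truth_path, index=False)
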