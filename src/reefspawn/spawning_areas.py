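"""Multispecies spawning collections and multi-year spawning areas.

A collection (gear set) that retrieved spawning-condition females of two or
more species is a multispecies spawning event. Per species, sets with
spawning females are clustered by single linkage at a configurable link
distance (default 1.1 km, the repeat-observation radius); clusters spanning
two or more sampling years are multi-year spawning areas, sized by the area
of the minimum convex polygon (MCP) of their member collections. Percent
years with spawning uses, as denominator, the years in which the cluster's
footprint (any location within the link distance of a member) was
histologically sampled for the species.

Coordinates are projected to a local Lambert azimuthal equal-area frame
centred on the points before any distance or area computation; convex hulls
are never taken on raw geographic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

EARTH_RADIUS_M = 6_371_008.8
DEFAULT_LINK_DISTANCE_M = 1100.0


def laea_project(lon, lat, lon0: float, lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Lambert azimuthal equal-area projection (metres) about (lon0, lat0)."""
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = np.radians(lat0)
    denom = 1 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
    )
    return x, y


def mcp_area(points_xy: np.ndarray) -> float:
    """Minimum-convex-polygon area in km^2 of projected (x, y) points in
    metres. Fewer than 3 non-collinear points give 0."""
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    if len(pts) < 1:
        raise ValueError("need at least one point")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    return float(hull.area) / 1e6


@dataclass
class SpawningEvent:
    set_id: str
    date: object
    year: int
    lon: float
    lat: float
    species: frozenset


@dataclass
class SpawningArea:
    species: str
    set_ids: tuple[str, ...]
    years: tuple[int, ...]
    n_events: int
    area_km2: float
    pct_years_with_spawning: float
    centroid: tuple[float, float]


def spawning_events(records: pd.DataFrame) -> pd.DataFrame:
    """One row per gear set with >= 1 spawning-condition female: set_id,
    date, year, coordinates and the species set observed spawning."""
    sp = records[records["spawning"] == 1]
    if sp.empty:
        return pd.DataFrame(
            columns=["set_id", "date", "year", "lon", "lat", "species_set", "n_species"]
        )
    grp = sp.groupby("set_id")
    out = grp.agg(
        date=("date", "first"),
        year=("year", "first"),
        lon=("lon", "first"),
        lat=("lat", "first"),
    )
    out["species_set"] = grp["species"].agg(lambda s: frozenset(s))
    out["n_species"] = out["species_set"].map(len)
    return out.reset_index()


def detect_multispecies(records: pd.DataFrame) -> pd.DataFrame:
    """Events whose species set has size >= 2."""
    ev = spawning_events(records)
    return ev[ev["n_species"] >= 2].reset_index(drop=True)


def cooccurrence_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Symmetric species x species count of sets where both were observed in
    spawning condition together (zero diagonal)."""
    ev = spawning_events(records)
    species = sorted(set(records["species"]))
    mat = pd.DataFrame(0, index=species, columns=species)
    for sset in ev["species_set"]:
        ss = sorted(sset)
        for i, a in enumerate(ss):
            for b in ss[i + 1:]:
                mat.loc[a, b] += 1
                mat.loc[b, a] += 1
    return mat


def _connected_components(xy: np.ndarray, link: float) -> np.ndarray:
    """Single-linkage clusters = connected components of the pairwise
    <= link-distance graph (union-find over KD-tree pairs)."""
    n = len(xy)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(link):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return np.array([find(i) for i in range(n)])


def cluster_multiyear(
    records: pd.DataFrame,
    link_distance: float = DEFAULT_LINK_DISTANCE_M,
    species: str | None = None,
) -> list[SpawningArea]:
    """Multi-year spawning areas for one species (or all, concatenated)."""
    if species is None:
        out: list[SpawningArea] = []
        for sp in sorted(set(records["species"])):
            out.extend(cluster_multiyear(records, link_distance, sp))
        return out

    sub = records[records["species"] == species]
    ev = spawning_events(sub)
    if ev.empty:
        return []
    lon0, lat0 = float(ev["lon"].mean()), float(ev["lat"].mean())
    ex, ey = laea_project(ev["lon"], ev["lat"], lon0, lat0)
    labels = _connected_components(np.column_stack([ex, ey]), link_distance)

    # all histologically sampled sets of the species, for the denominator
    all_sets = sub.groupby("set_id").agg(
        year=("year", "first"), lon=("lon", "first"), lat=("lat", "first")
    )
    sx, sy = laea_project(all_sets["lon"], all_sets["lat"], lon0, lat0)
    sample_tree = cKDTree(np.column_stack([sx, sy]))

    areas: list[SpawningArea] = []
    for lab in np.unique(labels):
        members = ev[labels == lab]
        years = tuple(sorted(set(members["year"])))
        if len(years) < 2:
            continue
        mx, my = laea_project(members["lon"], members["lat"], lon0, lat0)
        pts = np.column_stack([mx, my])
        near = set()
        for p in pts:
            near.update(sample_tree.query_ball_point(p, link_distance))
        sampled_years = set(all_sets.iloc[sorted(near)]["year"])
        pct = (
            100.0 * len(set(years)) / len(sampled_years) if sampled_years else np.nan
        )
        areas.append(
            SpawningArea(
                species=species,
                set_ids=tuple(members["set_id"]),
                years=years,
                n_events=len(members),
                area_km2=mcp_area(pts),
                pct_years_with_spawning=pct,
                centroid=(float(members["lon"].mean()), float(members["lat"].mean())),
            )
        )
    return areas


def area_summary(areas: list[SpawningArea]) -> pd.DataFrame:
    """Per-species summary of multi-year spawning locations: count, percent
    years with spawning and MCP size (mean +/- SD; sizes reported to the
    nearest km^2 in formatted output only)."""
    rows = []
    by_sp: dict[str, list[SpawningArea]] = {}
    for a in areas:
        by_sp.setdefault(a.species, []).append(a)
    for sp, group in sorted(by_sp.items()):
        sizes = np.array([a.area_km2 for a in group])
        pcts = np.array([a.pct_years_with_spawning for a in group], dtype=float)
        rows.append(
            {
                "species": sp,
                "n_multiyear_locations": len(group),
                "pct_years_mean": float(np.nanmean(pcts)),
                "pct_years_sd": float(np.nanstd(pcts, ddof=1)) if len(group) > 1 else 0.0,
                "area_km2_mean": float(sizes.mean()),
                "area_km2_sd": float(sizes.std(ddof=1)) if len(group) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
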