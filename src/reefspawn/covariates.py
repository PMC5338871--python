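"""Design variables for the spawning model.

Builds everything the logistic model consumes from the collections table: the
signed lunar-luminosity covariate, quantile or fixed binning of continuous
predictors, dummy-coded factors and factor-cross interactions, plus the
phenology tabulations (spawning fraction by species x month x lunar phase).

The collections CSV schema (exact column names) is::

    set_id,date,year,month,lon,lat,gear,depth_m,temp_c,salinity_ppt,habitat,species,spawning

with ``spawning`` the binary response: 1 = mature female with histological
evidence of imminent or very recent spawning (within ~48 h), 0 = mature
non-spawning female.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SYNODIC_MONTH_DAYS = 29.53059
#: a reference new moon: 2000-01-06 18:14 UTC
NEW_MOON_EPOCH = pd.Timestamp("2000-01-06 18:14:00")

PHASE_CATEGORIES = (
    "new",
    "waxing crescent",
    "waxing half",
    "waxing gibbous",
    "full",
    "waning gibbous",
    "waning half",
    "waning crescent",
)

COLLECTION_COLUMNS = [
    "set_id", "date", "year", "month", "lon", "lat", "gear", "depth_m",
    "temp_c", "salinity_ppt", "habitat", "species", "spawning",
]


# ---------------------------------------------------------------------------
# Lunar covariate
# ---------------------------------------------------------------------------

def mean_new_moons(start: str | pd.Timestamp, end: str | pd.Timestamp) -> pd.DatetimeIndex:
    """New-moon dates between ``start`` and ``end`` from the mean synodic
    lunation (constant 29.53059 d period anchored at the 2000-01-06 epoch).

    A mean-lunation ephemeris is accurate to well under a day over the survey
    decades, which is ample for an illuminated-fraction covariate.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    k0 = np.floor((start - NEW_MOON_EPOCH) / pd.Timedelta(days=SYNODIC_MONTH_DAYS)) - 1
    k1 = np.ceil((end - NEW_MOON_EPOCH) / pd.Timedelta(days=SYNODIC_MONTH_DAYS)) + 1
    ks = np.arange(k0, k1 + 1)
    times = NEW_MOON_EPOCH + pd.to_timedelta(ks * SYNODIC_MONTH_DAYS, unit="D")
    return pd.DatetimeIndex(times)


@dataclass(frozen=True)
class Lunar3Value:
    value: float            # signed luminosity in [-1, 1]; positive = waxing
    category: str           # one of PHASE_CATEGORIES
    phase_angle: float      # theta in [0, 2*pi)


def _phase_category(theta: np.ndarray) -> np.ndarray:
    # octants centered on the eight named phases
    idx = np.floor(((theta + np.pi / 8) % (2 * np.pi)) / (np.pi / 4)).astype(int)
    return np.asarray(PHASE_CATEGORIES, dtype=object)[idx]


def lunar3(
    dates,
    reference_new_moons: pd.DatetimeIndex | None = None,
    quarter_round: bool = False,
):
    """Signed lunar luminosity for one date or a vector of dates.

    The phase angle is ``theta = 2*pi * (days since previous new moon) /
    29.53059``; the illuminated fraction ``f = (1 - cos(theta)) / 2`` takes a
    positive sign on waxing moons (``theta`` in [0, pi]) and negative on
    waning. ``quarter_round`` snaps the signed value to the nearest multiple
    of 0.25 (the "nearest quarter moon" treatment).

    Returns a single :class:`Lunar3Value` for a scalar date, else a DataFrame
    with columns ``lunar3``, ``lunar_cat`` and ``phase_angle``.
    """
    scalar = np.isscalar(dates) or isinstance(dates, (str, pd.Timestamp))
    dts = pd.DatetimeIndex(pd.to_datetime([dates] if scalar else dates))
    if reference_new_moons is None:
        reference_new_moons = mean_new_moons(
            dts.min() - pd.Timedelta(days=35), dts.max() + pd.Timedelta(days=1)
        )
    ref = pd.DatetimeIndex(reference_new_moons).sort_values()
    if (dts < ref[0]).any():
        raise ValueError("date precedes the first reference new moon")
    pos = ref.searchsorted(dts, side="right") - 1
    days = (dts - ref[pos.clip(0)]).total_seconds() / 86400.0
    theta = (2 * np.pi * np.asarray(days) / SYNODIC_MONTH_DAYS) % (2 * np.pi)
    frac = (1 - np.cos(theta)) / 2
    value = np.where(theta <= np.pi, frac, -frac)
    if quarter_round:
        value = np.round(value / 0.25) * 0.25
    cat = _phase_category(theta)
    if scalar:
        return Lunar3Value(float(value[0]), str(cat[0]), float(theta[0]))
    return pd.DataFrame(
        {"lunar3": value, "lunar_cat": cat, "phase_angle": theta},
        index=dts if not hasattr(dates, "index") else dates.index,
    )


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass
class BinResult:
    codes: np.ndarray        # integer bin index per observation (-1 = missing)
    edges: np.ndarray        # full edge vector, length n_bins + 1
    labels: list[str]
    warnings: list[str] = field(default_factory=list)


def _apply_edges(x: np.ndarray, edges: np.ndarray, clip: bool = False) -> np.ndarray:
    """Left-closed / right-open bins, last bin closed. -1 outside unless
    ``clip`` maps out-of-range values to the nearest bin."""
    x = np.asarray(x, dtype=float)
    codes = np.searchsorted(edges, x, side="right") - 1
    codes = np.where(x == edges[-1], len(edges) - 2, codes)  # close last bin
    if clip:
        codes = np.clip(codes, 0, len(edges) - 2)
    else:
        codes = np.where((x < edges[0]) | (x > edges[-1]), -1, codes)
    codes = np.where(np.isnan(x), -1, codes)
    return codes.astype(int)


def _bin_labels(edges: np.ndarray) -> list[str]:
    return [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 2)] + [
        f"[{edges[-2]:g},{edges[-1]:g}]"
    ]


def bin_quantile(x, k: int = 4) -> BinResult:
    """Bin a numeric vector at its empirical quantiles (type-7/linear).

    Duplicate edges from heavy ties are collapsed (fewer bins come back, with
    a warning record); a constant vector degenerates to a single bin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    warns: list[str] = []
    if finite.size == 0:
        raise ValueError("no finite values to bin")
    qs = np.quantile(finite, np.linspace(0, 1, k + 1))
    edges = np.unique(qs)
    if len(edges) < 2:
        edges = np.array([edges[0], edges[0]])
        warns.append("constant vector: single degenerate bin")
        codes = np.where(np.isfinite(x), 0, -1)
        return BinResult(codes, edges, [f"[{edges[0]:g},{edges[0]:g}]"], warns)
    if len(edges) < k + 1:
        warns.append(f"collapsed duplicate quantile edges: {len(edges) - 1} bins instead of {k}")
    codes = _apply_edges(x, edges)
    return BinResult(codes, edges, _bin_labels(edges), warns)


def bin_fixed(x, edges) -> BinResult:
    """Bin at fixed edges (e.g. the 20 m depth bins over 10-70 m)."""
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing")
    return BinResult(_apply_edges(x, edges), edges, _bin_labels(edges))


#: fixed schemes named in the study design
FIXED_DEPTH_EDGES = np.array([10.0, 30.0, 50.0, 70.0])        # 20 m bins, 10-70 m
FIXED_LATITUDE_EDGES = np.array([30.5, 31.5, 32.5, 33.5, 34.5])  # 1 deg bins


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

@dataclass
class TermDef:
    """How one model term maps onto the records table."""

    kind: str                      # "factor" | "continuous" | "binned"
    source: str                    # column in the (buffer-merged) records
    k: int = 4                     # quantile bins when kind == "binned"
    edges: np.ndarray | None = None  # fixed edges override


DEFAULT_TERMS: dict[str, TermDef] = {
    "month": TermDef("factor", "month"),
    "gear": TermDef("factor", "gear"),
    "habitat": TermDef("factor", "habitat"),
    "year_f": TermDef("factor", "year"),
    "temp_c": TermDef("continuous", "temp_c"),
    "lunar3": TermDef("continuous", "lunar3"),
    "lunar_cat": TermDef("factor", "lunar_cat"),
    "lunar_bin": TermDef("binned", "lunar3"),
    "lat_bin": TermDef("binned", "lat"),
    "depth_bin": TermDef("binned", "depth_m"),
}

#: buffer-summary covariates (Table-1 style mean/max terrain statistics) are
#: quantile-binned factors; any ``mean_*``/``max_*`` column resolves here.
_BUFFER_PREFIXES = ("mean_", "max_")


@dataclass
class DesignMatrix:
    """Response, dummy-coded model matrix and the metadata needed to encode
    new data identically (bin edges, factor levels, term order)."""

    y: np.ndarray
    X: pd.DataFrame                # includes an "Intercept" column
    groups: np.ndarray | None      # random-effect grouping labels (year)
    terms: tuple[str, ...]
    meta: dict[str, dict]
    n_dropped: int = 0
    warnings: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "DesignMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            y=self.y[idx],
            X=self.X.iloc[idx].reset_index(drop=True),
            groups=None if self.groups is None else self.groups[idx],
        )


class DesignBuilder:
    """Builds design matrices for arbitrary term subsets of one records
    table, so stepwise selection can request candidate models cheaply.

    ``buffers`` (a :func:`reefspawn.terrain.summarize_buffer` frame keyed by
    ``set_id``) is merged in when terrain terms are requested. Rows with
    missing or non-positive temperature are dropped only for models that use
    temperature, unless ``restrict_temp`` forces the restriction up front so
    all candidate models share identical rows (required for AIC comparison).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        buffers: pd.DataFrame | None = None,
        term_defs: dict[str, TermDef] | None = None,
        restrict_temp: bool = False,
        group_col: str | None = "year",
    ) -> None:
        df = records.reset_index(drop=True).copy()
        if "lunar3" not in df.columns and "date" in df.columns:
            lun = lunar3(pd.to_datetime(df["date"]))
            df["lunar3"] = lun["lunar3"].to_numpy()
            df["lunar_cat"] = lun["lunar_cat"].to_numpy()
        if buffers is not None:
            extra = buffers.drop(columns=["n_cells", "missing"], errors="ignore")
            df = df.merge(extra, left_on="set_id", right_index=True, how="left")
        self.n_input = len(df)
        if restrict_temp:
            ok = df["temp_c"].notna() & (df["temp_c"] > 0)
            df = df.loc[ok].reset_index(drop=True)
        self.records = df
        self.term_defs = dict(DEFAULT_TERMS)
        if term_defs:
            self.term_defs.update(term_defs)
        self.group_col = group_col
        self._restricted = restrict_temp

    # -- term resolution ----------------------------------------------------
    def resolve(self, term: str) -> TermDef:
        if term in self.term_defs:
            return self.term_defs[term]
        if term.startswith(_BUFFER_PREFIXES):
            if term not in self.records.columns:
                raise KeyError(
                    f"terrain term {term!r} requested but no buffer column present"
                )
            return TermDef("binned", term)
        raise KeyError(f"unknown model term {term!r}")

    def screen_values(self, terms: list[str]) -> tuple[pd.DataFrame, dict[str, str]]:
        """Per-term vectors for the correlation screen: the underlying
        continuous value where one exists, otherwise the raw factor labels."""
        cols, kinds = {}, {}
        for t in terms:
            base = t.split(":")[0] if ":" in t else t
            td = self.resolve(base)
            col = self.records[td.source]
            if td.kind == "factor" and not np.issubdtype(np.asarray(col).dtype, np.number):
                cols[t], kinds[t] = col, "cat"
            else:
                cols[t], kinds[t] = pd.to_numeric(col, errors="coerce"), "num"
        return pd.DataFrame(cols), kinds

    # -- encoding -----------------------------------------------------------
    def _encode_term(self, term: str, df: pd.DataFrame):
        td = self.resolve(term)
        col = df[td.source]
        meta: dict = {"kind": td.kind, "source": td.source}
        if td.kind == "continuous":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(float)
            meta["range"] = (float(np.nanmin(vals)), float(np.nanmax(vals)))
            return pd.DataFrame({term: vals}, index=df.index), meta, []
        if td.kind == "binned":
            vals = pd.to_numeric(col, errors="coerce").to_numpy(float)
            if td.edges is not None:
                br = bin_fixed(vals, td.edges)
            else:
                br = bin_quantile(vals, td.k)
            labels = np.asarray(br.labels, dtype=object)
            lab = np.where(br.codes >= 0, labels[br.codes.clip(0)], None)
            meta["edges"] = br.edges.tolist()
            meta["labels"] = br.labels
            return self._dummies(term, pd.Series(lab, index=df.index), meta), meta, br.warnings
        # plain factor
        lab = col.astype(object).where(col.notna(), None)
        return self._dummies(term, lab, meta), meta, []

    @staticmethod
    def _dummies(term: str, labels: pd.Series, meta: dict) -> pd.DataFrame:
        observed = sorted({str(v) for v in labels.dropna()})
        meta["levels"] = observed
        if len(observed) < 2:
            meta["degenerate"] = True
            return pd.DataFrame(index=labels.index)
        ref, rest = observed[0], observed[1:]
        meta["reference"] = ref
        out = {}
        s = labels.astype(object).map(lambda v: None if v is None else str(v))
        for lev in rest:
            out[f"{term}[{lev}]"] = (s == lev).astype(float)
        dm = pd.DataFrame(out, index=labels.index)
        dm[s.isna()] = np.nan
        return dm

    def build(self, terms, groups: bool = True) -> DesignMatrix:
        """Design matrix for an ordered term list; interactions spelled
        ``a:b`` are factor crosses of the two dummy blocks."""
        terms = tuple(terms)
        df = self.records
        blocks: list[pd.DataFrame] = [pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)]
        meta: dict[str, dict] = {}
        warns: list[str] = []
        main_cache: dict[str, pd.DataFrame] = {}

        temp_terms = any(
            self.resolve(t.split(":")[0]).source == "temp_c"
            or (":" in t and self.resolve(t.split(":")[1]).source == "temp_c")
            for t in terms
        )
        if temp_terms and not self._restricted:
            bad = ~(df["temp_c"].notna() & (df["temp_c"] > 0))
            if bad.any():
                df = df.loc[~bad]
                blocks[0] = blocks[0].loc[df.index]
                warns.append(f"dropped {int(bad.sum())} rows with missing/non-positive temperature")

        def main(t: str) -> pd.DataFrame:
            if t not in main_cache:
                enc, m, w = self._encode_term(t, df)
                meta[t] = m
                warns.extend(w)
                main_cache[t] = enc
            return main_cache[t]

        for term in terms:
            if ":" in term:
                a, b = term.split(":")
                ea, eb = main(a), main(b)
                cross = {}
                for ca in ea.columns:
                    for cb in eb.columns:
                        cross[f"{ca}:{cb}"] = ea[ca] * eb[cb]
                blocks.append(pd.DataFrame(cross, index=df.index))
                meta[term] = {"kind": "interaction", "of": (a, b)}
            else:
                blocks.append(main(term))

        X = pd.concat(blocks, axis=1)
        complete = X.notna().all(axis=1) & df["spawning"].notna()
        n_dropped = int((~complete).sum())
        X = X.loc[complete]
        dfc = df.loc[complete]
        # remove factor bins with no observations (all-zero dummies)
        keep = [c for c in X.columns if c == "Intercept" or X[c].abs().sum() > 0]
        removed = [c for c in X.columns if c not in keep]
        if removed:
            warns.append(f"removed {len(removed)} empty factor level column(s)")
        X = X[keep]
        y = dfc["spawning"].to_numpy(float)
        g = None
        if groups and self.group_col is not None and self.group_col in dfc.columns:
            g = dfc[self.group_col].to_numpy()
        return DesignMatrix(
            y=y,
            X=X.reset_index(drop=True),
            groups=g,
            terms=terms,
            meta=meta,
            n_dropped=n_dropped + (self.n_input - len(self.records)),
            warnings=tuple(warns),
        )


def encode_new(
    design: DesignMatrix, newdata: pd.DataFrame, strict: bool = False
) -> pd.DataFrame:
    """Encode new rows with the bin edges and factor levels stored in a
    fitted design. Unseen factor levels (and out-of-range binned values) map
    to the reference level with a warning, or raise in ``strict`` mode."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(newdata))}
    n = len(newdata)
    labels_by_term: dict[str, np.ndarray] = {}

    def term_labels(term: str) -> np.ndarray:
        if term in labels_by_term:
            return labels_by_term[term]
        m = design.meta[term]
        src = m["source"]
        if m["kind"] == "binned":
            edges = np.asarray(m["edges"])
            vals = pd.to_numeric(newdata[src], errors="coerce").to_numpy(float)
            codes = _apply_edges(vals, edges, clip=True)
            out_of_range = int(((vals < edges[0]) | (vals > edges[-1])).sum())
            if out_of_range:
                if strict:
                    raise ValueError(f"{out_of_range} values outside stored bins for {term}")
                warnings.warn(
                    f"{term}: {out_of_range} values outside stored bin range mapped "
                    "to nearest bin",
                    stacklevel=2,
                )
            labs = np.asarray(m["labels"], dtype=object)[codes]
        else:
            labs = newdata[src].astype(object).map(str).to_numpy()
            known = set(m["levels"])
            unseen = ~np.isin(labs, list(known))
            if unseen.any():
                if strict:
                    raise ValueError(f"unseen levels for {term}: {set(labs[unseen])}")
                warnings.warn(
                    f"{term}: {int(unseen.sum())} unseen level value(s) mapped to "
                    "reference",
                    stacklevel=2,
                )
                labs = labs.copy()
                labs[unseen] = m.get("reference", m["levels"][0])
        labels_by_term[term] = labs
        return labs

    for term in design.terms:
        m = design.meta[term]
        if m["kind"] == "continuous":
            cols[term] = pd.to_numeric(newdata[m["source"]], errors="coerce").to_numpy(float)
        elif m["kind"] == "interaction":
            continue  # handled below, after both margins' labels exist
        else:
            labs = term_labels(term)
            for lev in m["levels"][1:]:
                cols[f"{term}[{lev}]"] = (labs == lev).astype(float)

    # interactions: product of the member dummies
    for term in design.terms:
        m = design.meta[term]
        if m["kind"] != "interaction":
            continue
        a, b = m["of"]
        la, lb = term_labels(a), term_labels(b)
        for leva in design.meta[a]["levels"][1:]:
            for levb in design.meta[b]["levels"][1:]:
                cols[f"{a}[{leva}]:{b}[{levb}]"] = (
                    (la == leva) & (lb == levb)
                ).astype(float)

    out = pd.DataFrame(cols, index=newdata.index)
    # align exactly to the fitted columns (empty levels removed at fit time)
    out = out.reindex(columns=design.X.columns, fill_value=0.0)
    assert len(out) == n
    return out


# ---------------------------------------------------------------------------
# Phenology
# ---------------------------------------------------------------------------

def phenology_table(records: pd.DataFrame, by_lunar: bool = True) -> pd.DataFrame:
    """Counts of examined and spawning females, and the spawning fraction,
    per (species, month[, lunar category]). Cells with zero examined fish are
    flagged ``empty``."""
    df = records.copy()
    if by_lunar and "lunar_cat" not in df.columns:
        df["lunar_cat"] = lunar3(pd.to_datetime(df["date"]))["lunar_cat"].to_numpy()
    keys = ["species", "month"] + (["lunar_cat"] if by_lunar else [])
    grp = df.groupby(keys, observed=True)["spawning"]
    out = grp.agg(n_examined="count", n_spawning="sum").reset_index()
    out["fraction"] = np.where(
        out["n_examined"] > 0, out["n_spawning"] / out["n_examined"], np.nan
    )
    out["empty"] = out["n_examined"] == 0
    return out
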