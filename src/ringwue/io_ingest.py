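"""Reading ring-width, metadata and climate files and assembling the
modelling table.

Ring widths come in either the decadal Tucson (.rwl) interchange format or
a tidy CSV. Trees are assigned to establishment cohorts (Past: innermost
ring before 1895; Modern: 1895-1950), annual diameters are reconstructed
backwards from the census DBH, and one row per tree-year is produced with
the log response, two lagged log growths and raw covariates ready for
group-wise scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Establishment-year boundaries defining the two cohorts.
PAST_CUTOFF = 1895          # established strictly before -> Past
MODERN_CUTOFF = 1950        # established in [1895, 1950] -> Modern

#: Analysis windows: Past-cohort trees contribute 1895-1949 rings,
#: Modern-cohort trees contribute 1950-2015 rings.
PAST_WINDOW = (1895, 1949)
MODERN_WINDOW = (1950, 2015)

STRUCTURES = ("savanna", "forest")

#: Tucson end-of-series sentinels and the measurement unit each implies.
_SENTINEL_UNITS = {999: 0.01, -9999: 0.001}


class TucsonParseError(ValueError):
    """Raised when a .rwl file violates the decadal layout."""


@dataclass
class RingWidthSeries:
    """One measured core: consecutive annual ring widths in mm."""

    tree_id: str
    site_id: str
    first_year: int
    widths: np.ndarray  # mm/yr; NaN marks a missing (not zero) ring

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        finite = self.widths[~np.isnan(self.widths)]
        if np.any(np.isinf(finite)):
            raise ValueError(f"{self.tree_id}: non-finite ring width")
        if np.any(finite < 0):
            raise ValueError(f"{self.tree_id}: negative ring width")

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)


@dataclass
class TreeMeta:
    """Census metadata for one tree."""

    tree_id: str
    site_id: str
    census_dbh: float  # cm
    census_year: int
    structure: str

    def __post_init__(self) -> None:
        if self.census_dbh <= 0:
            raise ValueError(f"{self.tree_id}: census_dbh must be positive")
        if self.structure not in STRUCTURES:
            raise ValueError(
                f"{self.tree_id}: structure must be one of {STRUCTURES}, "
                f"got {self.structure!r}")


def assign_cohort(establishment_year: int) -> str:
    """Map a tree's establishment year (innermost ring) to its cohort.

    Trees established before 1895 grew under low atmospheric CO2 ("Past");
    trees established 1895-1950 under higher CO2 ("Modern"); later trees
    are excluded from the cohort contrast.
    """
    if establishment_year < PAST_CUTOFF:
        return "Past"
    if establishment_year <= MODERN_CUTOFF:
        return "Modern"
    return "Excluded"


# ---------------------------------------------------------------------------
# Tucson decadal .rwl format
# ---------------------------------------------------------------------------

def read_tucson_rwl(path: str | Path, units: float | None = None,
                    site_id: str | None = None) -> list[RingWidthSeries]:
    """Read a decadal Tucson ring-width file.

    Each data line holds a series id, the year of its first value, and up
    to ten values filling out the decade. A series ends with sentinel 999
    (0.01 mm records) or -9999 (0.001 mm records); the sentinel fixes the
    unit conversion unless ``units`` (mm per recorded integer unit, i.e.
    0.01 or 0.001) overrides it.

    Missing rings may be coded 0 inside a series; they are kept as 0 and
    interpreted downstream (log response drops them).
    """
    path = Path(path)
    sid = site_id if site_id is not None else path.stem
    out: list[RingWidthSeries] = []

    current_id: str | None = None
    values: list[float] = []
    first_year = 0
    next_year = 0

    def _finish(raw_unit: float | None, lineno: int) -> None:
        nonlocal current_id, values
        scale = units if units is not None else raw_unit
        if scale is None:
            raise TucsonParseError(
                f"{path}:{lineno}: series {current_id} ended without a "
                "recognised sentinel (999 or -9999) and no unit override")
        arr = np.array(values, dtype=float) * scale
        out.append(RingWidthSeries(current_id, sid, first_year, arr))
        current_id, values = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise TucsonParseError(f"{path}:{lineno}: malformed line")
            series_id = tokens[0]
            try:
                year = int(tokens[1])
            except ValueError as exc:
                raise TucsonParseError(
                    f"{path}:{lineno}: bad decade year {tokens[1]!r}") from exc

            if current_id is not None and series_id != current_id:
                # series changed without a sentinel line
                _finish(None, lineno)
            if current_id is None:
                current_id, first_year, next_year = series_id, year, year
            elif year != next_year:
                raise TucsonParseError(
                    f"{path}:{lineno}: non-consecutive decade row for "
                    f"{series_id}: expected year {next_year}, got {year}")

            for tok in tokens[2:]:
                try:
                    v = int(tok)
                except ValueError as exc:
                    raise TucsonParseError(
                        f"{path}:{lineno}: bad value {tok!r}") from exc
                if v in _SENTINEL_UNITS:
                    _finish(_SENTINEL_UNITS[v], lineno)
                    break
                if v < 0:
                    raise TucsonParseError(
                        f"{path}:{lineno}: unknown sentinel {v}")
                values.append(v)
                next_year += 1
    if current_id is not None:
        _finish(None, lineno)
    if not out:
        logger.warning("%s: no ring-width series found (empty file?)", path)
    logger.info("%s: read %d series", path, len(out))
    return out


def write_tucson_rwl(series: Iterable[RingWidthSeries], path: str | Path,
                     units: float = 0.01) -> None:
    """Write series in decadal Tucson layout.

    ``units`` is mm per recorded integer (0.01 or 0.001); the matching
    end-of-series sentinel (999 or -9999) is appended so the file
    round-trips through :func:`read_tucson_rwl`.
    """
    sentinel = {0.01: 999, 0.001: -9999}.get(units)
    if sentinel is None:
        raise ValueError("units must be 0.01 or 0.001 mm")
    with open(path, "w") as fh:
        for s in series:
            ints = np.round(s.widths / units).astype(int)
            row: list[str] = []
            row_year = s.first_year
            for i, v in enumerate(ints):
                y = s.first_year + i
                if not row:
                    row_year = y
                row.append(f"{v:6d}")
                if y % 10 == 9:  # decade boundary closes the row
                    fh.write(f"{s.tree_id:<8s}{row_year:5d}"
                             + "".join(row) + "\n")
                    row = []
            if not row:
                row_year = s.last_year + 1
            row.append(f"{sentinel:6d}")
            fh.write(f"{s.tree_id:<8s}{row_year:5d}" + "".join(row) + "\n")


# ---------------------------------------------------------------------------
# Tidy CSV formats
# ---------------------------------------------------------------------------

def read_ring_csv(path: str | Path) -> list[RingWidthSeries]:
    """Read a tidy ring-width CSV (tree_id, site_id, year, width_mm)."""
    df = pd.read_csv(path)
    out = []
    for (tree, site), grp in df.groupby(["tree_id", "site_id"], sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError(f"{tree}: ring years not consecutive")
        out.append(RingWidthSeries(str(tree), str(site), int(years[0]),
                                   grp["width_mm"].to_numpy(float)))
    logger.info("%s: read %d series, %d rows", path, len(out), len(df))
    return out


def write_ring_csv(series: Iterable[RingWidthSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for y, w in zip(s.years, s.widths):
            rows.append((s.tree_id, s.site_id, int(y), w))
    pd.DataFrame(rows, columns=["tree_id", "site_id", "year", "width_mm"]
                 ).to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> list[TreeMeta]:
    """Read tree metadata CSV (tree_id, site_id, census_dbh_cm, census_year,
    structure)."""
    df = pd.read_csv(path)
    metas = [TreeMeta(str(r.tree_id), str(r.site_id), float(r.census_dbh_cm),
                      int(r.census_year), str(r.structure))
             for r in df.itertuples()]
    logger.info("%s: read %d tree records", path, len(metas))
    return metas


# ---------------------------------------------------------------------------
# DBH reconstruction and table assembly
# ---------------------------------------------------------------------------

DBH_FLOOR_CM = 0.1


def reconstruct_dbh(series: RingWidthSeries, meta: TreeMeta) -> pd.Series:
    """Annual end-of-year diameter (cm) reconstructed from ring widths.

    Anchored at the census: DBH(census_year) = census_dbh. Stepping back one
    year removes that year's diameter increment, twice the radial ring width
    (mm converted to cm). Values are floored at 0.1 cm; bark is ignored (a
    constant offset absorbed later by covariate scaling).
    """
    if meta.census_year < series.first_year:
        raise ValueError(
            f"{series.tree_id}: census year {meta.census_year} precedes "
            f"first ring year {series.first_year}")
    years = series.years
    incr = 2.0 * np.nan_to_num(series.widths) / 10.0  # cm of diameter per year
    # diameter at end of each ring year, relative to end of census year
    cum = np.cumsum(incr)
    anchor_year = min(meta.census_year, series.last_year)
    anchor_idx = int(anchor_year - series.first_year)
    dbh = meta.census_dbh + (cum - cum[anchor_idx])
    if np.any(dbh < DBH_FLOOR_CM):
        logger.warning("%s: reconstructed DBH floored at %.1f cm",
                       series.tree_id, DBH_FLOOR_CM)
        dbh = np.maximum(dbh, DBH_FLOOR_CM)
    return pd.Series(dbh, index=pd.Index(years, name="year"), name="dbh_cm")


def _window_for(cohort: str) -> tuple[int, int]:
    return PAST_WINDOW if cohort == "Past" else MODERN_WINDOW


def assemble_observations(series: Sequence[RingWidthSeries],
                          meta: Sequence[TreeMeta],
                          annual_climate: pd.DataFrame) -> pd.DataFrame:
    """Build the growth modelling table: one row per retained tree-year.

    Steps, per tree: average same-tree cores by year (1-3 cores per tree is
    common); take establishment year = innermost ring year and assign the
    cohort; restrict to the cohort's analysis window (Past 1895-1949,
    Modern 1950-2015); log-transform widths; attach lag-1/lag-2 log growth
    from the same tree; attach the reconstructed end-of-previous-year DBH
    (the size entering the growth year) and the site-year climate. Zero or
    missing rings are treated as missing: the year itself and the two
    following years (whose lags depend on it) are dropped. The first two
    years of each series have no lags and are never retained.

    ``annual_climate`` must carry site_id, year, wy_precip, june_tmax and
    (if present) jja_pdsi; climate must cover every retained tree-year.
    """
    meta_by_tree = {m.tree_id: m for m in meta}
    rows = []
    excluded: list[str] = []

    by_tree: dict[str, list[RingWidthSeries]] = {}
    for s in series:
        by_tree.setdefault(s.tree_id, []).append(s)

    clim = annual_climate.set_index(["site_id", "year"]).sort_index()

    for tree_id, cores in sorted(by_tree.items()):
        if tree_id not in meta_by_tree:
            excluded.append(f"{tree_id}: no metadata")
            continue
        m = meta_by_tree[tree_id]
        y0 = min(c.first_year for c in cores)
        y1 = max(c.last_year for c in cores)
        years = np.arange(y0, y1 + 1)
        stack = np.full((len(cores), len(years)), np.nan)
        for i, c in enumerate(cores):
            stack[i, c.first_year - y0: c.last_year - y0 + 1] = c.widths
        with np.errstate(invalid="ignore"):
            width = np.nanmean(stack, axis=0)
        width[width == 0] = np.nan  # zero rings treated as missing

        cohort = assign_cohort(y0)
        if cohort == "Excluded":
            excluded.append(f"{tree_id}: established {y0}, outside cohorts")
            continue

        merged = RingWidthSeries(tree_id, m.site_id, int(y0),
                                 np.nan_to_num(width))
        dbh = reconstruct_dbh(merged, m)

        lo, hi = _window_for(cohort)
        logw = np.log(width)
        for j, year in enumerate(years):
            if year < lo or year > hi or j < 2:
                continue
            trip = logw[j - 2: j + 1]
            if not np.all(np.isfinite(trip)):
                continue
            key = (m.site_id, int(year))
            if key not in clim.index:
                raise KeyError(f"no climate for site {m.site_id}, year {year}")
            crow = clim.loc[key]
            rows.append({
                "tree_id": tree_id, "site_id": m.site_id, "year": int(year),
                "log_growth": logw[j],
                "lag1_log_growth": logw[j - 1],
                "lag2_log_growth": logw[j - 2],
                "dbh": float(dbh.loc[year - 1]) if year - 1 >= y0
                        else float(dbh.loc[y0]),
                "wy_precip": float(crow["wy_precip"]),
                "june_tmax": float(crow["june_tmax"]),
                "jja_pdsi": float(crow["jja_pdsi"])
                            if "jja_pdsi" in crow.index else np.nan,
                "cohort": cohort, "structure": m.structure,
            })
        if not rows or rows[-1]["tree_id"] != tree_id:
            excluded.append(f"{tree_id}: no valid rows in window")

    for reason in excluded:
        logger.info("excluded %s", reason)
    obs = pd.DataFrame(rows)
    logger.info("assembled %d observations from %d trees (%d excluded)",
                len(obs), obs["tree_id"].nunique() if len(obs) else 0,
                len(excluded))
    return obs


def assign_groups(obs: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Add the random-effect class column ``group``.

    ``grouping`` is "cohort" (Modern, Past) or "cohort_structure" (the four
    cohort x stand-structure combinations, e.g. "Past-Savanna").
    """
    obs = obs.copy()
    if grouping == "cohort":
        obs["group"] = obs["cohort"]
    elif grouping == "cohort_structure":
        obs["group"] = (obs["cohort"] + "-" +
                        obs["structure"].str.capitalize())
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return obs
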