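"""Annual climate covariates, drought-year filtering, group-wise scaling,
train/test splitting, and climate-matched year selection for isotope
sampling.

The growth model uses two climate covariates with strong growth
correlations in this system: total water-year precipitation (October of
the previous calendar year through September) and June maximum
temperature. To focus the climate-sensitivity contrast on drought years,
wet years are removed by a per-(site, cohort) quantile filter on mean
June-August PDSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

#: covariates scaled within each cohort/structure class
SCALED_COVARIATES = ("wy_precip", "june_tmax", "dbh")


def build_annual_climate(monthly: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a monthly climate table to the annual covariates.

    Input columns: site_id, year, month, precip (mm), tmax (degC), pdsi.
    Output: one row per (site_id, year) with wy_precip (sum of the 12
    water-year months), june_tmax, and jja_pdsi (mean June-August PDSI).
    Years with any missing water-year month are omitted (so the first year
    of every record drops: its Oct-Dec belong to the year before the
    record starts).
    """
    df = monthly.copy()
    if df.duplicated(["site_id", "year", "month"]).any():
        raise ValueError("duplicate (site, year, month) rows in climate table")
    # month Oct-Dec contributes to next year's water year
    df["wy"] = np.where(df["month"] >= 10, df["year"] + 1, df["year"])
    wy = (df.groupby(["site_id", "wy"])
            .agg(wy_precip=("precip", "sum"), n_months=("precip", "size"))
            .reset_index().rename(columns={"wy": "year"}))
    n_dropped = int((wy["n_months"] < 12).sum())
    wy = wy[wy["n_months"] == 12].drop(columns="n_months")
    if n_dropped:
        logger.info("dropped %d incomplete water years", n_dropped)

    june = (df[df["month"] == 6][["site_id", "year", "tmax"]]
            .rename(columns={"tmax": "june_tmax"}))
    jja = (df[df["month"].isin([6, 7, 8])]
           .groupby(["site_id", "year"])["pdsi"].mean()
           .rename("jja_pdsi").reset_index())
    out = wy.merge(june, on=["site_id", "year"]).merge(
        jja, on=["site_id", "year"])
    return out.sort_values(["site_id", "year"]).reset_index(drop=True)


def water_year_precip(monthly: pd.DataFrame, site_id: str, year: int) -> float:
    """Water-year (Oct-Sep) precipitation total for one site-year, mm.

    Undefined (raises KeyError) unless all 12 contributing months are
    present.
    """
    m = monthly[monthly["site_id"] == site_id]
    prev = m[(m["year"] == year - 1) & (m["month"] >= 10)]
    curr = m[(m["year"] == year) & (m["month"] <= 9)]
    if len(prev) != 3 or len(curr) != 9:
        raise KeyError(f"incomplete water year {year} for site {site_id}")
    return float(prev["precip"].sum() + curr["precip"].sum())


def drought_filter(obs: pd.DataFrame, q: float = 0.75,
                   keep: str = "dry") -> pd.DataFrame:
    """Retain drought years within each (site, cohort) group.

    Keeps observation years whose mean June-August PDSI is at or below the
    group's ``q`` quantile (``keep="dry"``: the driest fraction ``q`` is
    retained, the wettest 1-q discarded). ``keep="wet"`` flips the
    direction. The quantile is the linear-interpolation convention
    (numpy default). Groups with fewer than 4 distinct years are retained
    unfiltered with a warning.
    """
    if keep not in ("dry", "wet"):
        raise ValueError("keep must be 'dry' or 'wet'")
    if "jja_pdsi" not in obs.columns or obs["jja_pdsi"].isna().any():
        raise ValueError("jja_pdsi must be defined for every observation")
    parts = []
    for (site, cohort), grp in obs.groupby(["site_id", "cohort"], sort=True):
        year_pdsi = grp.drop_duplicates("year")["jja_pdsi"]
        if year_pdsi.nunique() < 4:
            logger.warning("group (%s, %s): <4 distinct years, unfiltered",
                           site, cohort)
            parts.append(grp)
            continue
        cut = float(np.quantile(year_pdsi, q if keep == "dry" else 1 - q,
                                method="linear"))
        mask = grp["jja_pdsi"] <= cut if keep == "dry" else grp["jja_pdsi"] >= cut
        parts.append(grp[mask])
    out = pd.concat(parts).sort_index()
    logger.info("drought filter (q=%.2f, keep=%s): retained %d of %d rows",
                q, keep, len(out), len(obs))
    return out


@dataclass
class ScalingParams:
    """Per-class means/sds used to z-score covariates, plus auxiliary
    class statistics (mean lagged log growth, historical covariate ranges)
    needed when building prediction grids."""

    table: pd.DataFrame  # indexed by group; columns <cov>_mean, <cov>_sd, ...

    def scale(self, obs: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored z-scoring to an observation table (must carry a
        ``group`` column and the raw covariates)."""
        out = obs.copy()
        t = self.table
        for cov, col in (("wy_precip", "precip_scaled"),
                         ("june_tmax", "tmax_scaled"),
                         ("dbh", "dbh_scaled")):
            mu = t.loc[out["group"], f"{cov}_mean"].to_numpy()
            sd = t.loc[out["group"], f"{cov}_sd"].to_numpy()
            out[col] = (out[cov].to_numpy() - mu) / sd
        out["interaction"] = out["precip_scaled"] * out["tmax_scaled"]
        return out

    def unscale(self, obs: pd.DataFrame) -> pd.DataFrame:
        """Invert :meth:`scale` for the three raw covariates."""
        out = obs.copy()
        t = self.table
        for cov, col in (("wy_precip", "precip_scaled"),
                         ("june_tmax", "tmax_scaled"),
                         ("dbh", "dbh_scaled")):
            mu = t.loc[out["group"], f"{cov}_mean"].to_numpy()
            sd = t.loc[out["group"], f"{cov}_sd"].to_numpy()
            out[cov] = out[col].to_numpy() * sd + mu
        return out


def scale_covariates(obs: pd.DataFrame,
                     params: ScalingParams | None = None
                     ) -> tuple[pd.DataFrame, ScalingParams]:
    """Z-score precipitation, temperature and DBH within each class.

    ``obs`` must already carry the ``group`` column (see
    :func:`ringwue.io_ingest.assign_groups`). If ``params`` is given the
    stored statistics are applied unchanged (e.g. to score held-out rows or
    prediction grids); otherwise statistics are estimated from ``obs``.
    The precipitation x temperature interaction column is (re)computed as
    the product of the two z-scores.
    """
    if "group" not in obs.columns:
        raise ValueError("obs must carry a 'group' column; see assign_groups")
    if params is None:
        recs = {}
        for g, grp in obs.groupby("group", sort=True):
            rec = {}
            for cov in SCALED_COVARIATES:
                x = grp[cov].to_numpy(float)
                sd = float(np.std(x, ddof=1))
                if not sd > 0:
                    raise ValueError(
                        f"zero within-group sd for {cov} in group {g}")
                rec[f"{cov}_mean"] = float(np.mean(x))
                rec[f"{cov}_sd"] = sd
                rec[f"{cov}_min"] = float(np.min(x))
                rec[f"{cov}_max"] = float(np.max(x))
            if "log_growth" in grp.columns:
                rec["log_growth_mean"] = float(grp["log_growth"].mean())
            recs[g] = rec
        params = ScalingParams(pd.DataFrame(recs).T.rename_axis("group"))
    return params.scale(obs), params


def train_test_split(obs: pd.DataFrame, frac: float = 0.75,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split stratified by (site, cohort).

    Within each stratum, round(frac * n) rows go to train. Reproducible
    under ``seed``; empty strata are impossible by construction but a
    stratum of one row goes wholly to train with a warning.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for (site, cohort), grp in obs.groupby(["site_id", "cohort"], sort=True):
        idx = grp.index.to_numpy()
        n_train = int(round(frac * len(idx)))
        if n_train == len(idx):
            logger.warning("stratum (%s, %s) too small to split; all in train",
                           site, cohort)
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:n_train]])
        test_idx.append(idx[perm[n_train:]])
    train = obs.loc[np.sort(np.concatenate(train_idx))]
    test = obs.loc[np.sort(np.concatenate(test_idx))]
    logger.info("train/test split: %d / %d rows (frac=%.3f, seed=%d)",
                len(train), len(test), frac, seed)
    return train, test


def select_matched_years(monthly: pd.DataFrame, past_window: tuple[int, int],
                         modern_window: tuple[int, int], k: int = 10
                         ) -> pd.DataFrame:
    """Select ``k`` climate-matched (past year, modern year) pairs for one
    site's isotope sampling.

    All candidate years' monthly climate variables (12 precip + 12 tmax +
    12 PDSI columns) are standardized and projected onto their first two
    principal components; pairs are formed greedily by smallest Euclidean
    distance in (PC1, PC2), each year used at most once, ties broken by the
    earlier past year. Sampling matched climates across cohorts isolates
    the CO2 contrast from climate differences.

    Returns a frame with past_year, modern_year, distance, sorted by
    distance.
    """
    wide = (monthly.pivot_table(index="year", columns="month",
                                values=["precip", "tmax", "pdsi"])
            .dropna())
    past_years = [y for y in wide.index
                  if past_window[0] <= y <= past_window[1]]
    modern_years = [y for y in wide.index
                    if modern_window[0] <= y <= modern_window[1]]
    cand = wide.loc[past_years + modern_years]
    if min(len(past_years), len(modern_years)) < k:
        logger.warning("only %d/%d candidate years; returning fewer pairs",
                       len(past_years), len(modern_years))
    z = StandardScaler().fit_transform(cand.to_numpy())
    pcs = PCA(n_components=2).fit_transform(z)
    scores = dict(zip(cand.index, pcs))

    pairs = []
    # all cross-pair distances; greedy selection of disjoint pairs
    cross = [(float(np.linalg.norm(scores[p] - scores[m])), p, m)
             for p in past_years for m in modern_years]
    cross.sort(key=lambda t: (t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_m: set[int] = set()
    for d, p, m in cross:
        if p in used_p or m in used_m:
            continue
        pairs.append({"past_year": p, "modern_year": m, "distance": d})
        used_p.add(p)
        used_m.add(m)
        if len(pairs) == k:
            break
    return pd.DataFrame(pairs)
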