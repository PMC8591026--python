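"""Posterior-predictive growth over climate grids and scenario summaries.

Predictions evaluate the fitted growth model over a temperature x
precipitation grid in natural units (degC, mm), holding the remaining
covariates at their class means: DBH at the class mean diameter and the
two lag terms at the class mean log growth. Percent-change contrasts are
taken per posterior draw against a reference temperature (the regional
median June maximum, 26 degC by default), so the reported intervals are
genuine posterior intervals of the contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ringwue.climate_prep import ScalingParams
from ringwue.growth_model import PosteriorSamples

logger = logging.getLogger(__name__)

REFERENCE_TMAX = 26.0   # degC, regional median June maximum temperature
LOW_PRECIP = 515.0      # mm, dry-condition scenario
HIGH_PRECIP = 950.0     # mm, wet-condition scenario


@dataclass
class CovariateGrid:
    """Unscaled prediction grid for one random-effect class."""

    group: str
    tmax: np.ndarray                 # degC
    precip: np.ndarray               # mm
    lag_log_growth: float | None = None   # defaults to class mean
    dbh: float | None = None              # cm; defaults to class mean

    def points(self) -> pd.DataFrame:
        t, p = np.meshgrid(np.asarray(self.tmax, float),
                           np.asarray(self.precip, float), indexing="ij")
        return pd.DataFrame({"tmax": t.ravel(), "precip": p.ravel()})


def _draw_matrix(samples: PosteriorSamples, name: str) -> np.ndarray:
    return samples.flat(name)


def posterior_predict(samples: PosteriorSamples, grid: CovariateGrid,
                      scaling: ScalingParams,
                      include_process_error: bool = True,
                      seed: int = 0) -> pd.DataFrame:
    """Posterior-predictive ring width (mm/yr) over a climate grid.

    Per retained draw, growth = exp(g + eps) with eps ~ N(0, sigma2_p)
    when process error is included (a full posterior predictive), else
    exp(g) (the conditional median). The site intercept is taken at its
    population mean mu_alpha, i.e. predictions are for a typical site.
    Summaries are the median and the 2.5/97.5 percentiles over draws.

    Grid points outside the historical covariate range seen by ``scaling``
    are flagged ``extrapolated`` rather than refused.
    """
    g = grid.group
    if g not in scaling.table.index:
        raise KeyError(f"no scaling parameters for group {g!r}")
    row = scaling.table.loc[g]
    pts = grid.points()
    t_z = (pts["tmax"] - row["june_tmax_mean"]) / row["june_tmax_sd"]
    p_z = (pts["precip"] - row["wy_precip_mean"]) / row["wy_precip_sd"]
    lag = grid.lag_log_growth
    if lag is None:
        lag = float(row.get("log_growth_mean", 0.0))
    dbh = grid.dbh if grid.dbh is not None else float(row["dbh_mean"])
    d_z = (dbh - row["dbh_mean"]) / row["dbh_sd"]

    covs = samples.meta["covariates"]
    x = {"precip": p_z.to_numpy(), "tmax": t_z.to_numpy(),
         "interaction": (p_z * t_z).to_numpy(),
         "lag1": np.full(len(pts), lag), "lag2": np.full(len(pts), lag),
         "dbh": np.full(len(pts), d_z)}
    X = np.column_stack([x[c] for c in covs])            # (n_pts, K)
    B = np.stack([_draw_matrix(samples, f"beta_{c}[{g}]") for c in covs])
    mu_a = _draw_matrix(samples, "mu_alpha")              # (D,)
    lin = mu_a[None, :] + X @ B                           # (n_pts, D)

    if include_process_error:
        rng = np.random.default_rng(seed)
        s2p = _draw_matrix(samples, "sigma2_p")
        lin = lin + rng.standard_normal(lin.shape) * np.sqrt(s2p)[None, :]
    growth = np.exp(lin)

    out = pts.copy()
    out["group"] = g
    out["growth_median"] = np.median(growth, axis=1)
    out["growth_lo"] = np.percentile(growth, 2.5, axis=1)
    out["growth_hi"] = np.percentile(growth, 97.5, axis=1)
    out["extrapolated"] = (
        (pts["tmax"] < row["june_tmax_min"]) | (pts["tmax"] > row["june_tmax_max"])
        | (pts["precip"] < row["wy_precip_min"])
        | (pts["precip"] > row["wy_precip_max"]))
    if out["extrapolated"].any():
        logger.info("%d grid points outside historical range (flagged)",
                    int(out["extrapolated"].sum()))
    out.attrs["growth_draws"] = growth   # kept for per-draw contrasts
    return out


def percent_change_vs_reference(pred: pd.DataFrame,
                                ref_tmax: float = REFERENCE_TMAX
                                ) -> pd.DataFrame:
    """Percent growth change relative to the reference temperature.

    For every precipitation level, contrasts each grid point against the
    grid point at ``ref_tmax`` and the same precipitation, per posterior
    draw: 100*(growth(t) - growth(ref))/growth(ref). Requires the draws
    carried by :func:`posterior_predict`.
    """
    draws = pred.attrs.get("growth_draws")
    if draws is None:
        raise ValueError("pred must come from posterior_predict "
                         "(per-draw growth missing)")
    out = pred.copy()
    pct_med = np.empty(len(pred))
    pct_lo = np.empty(len(pred))
    pct_hi = np.empty(len(pred))
    for precip, idx in pred.groupby("precip").groups.items():
        pos = pred.index.get_indexer(idx)
        sub_t = pred.loc[idx, "tmax"].to_numpy()
        ref_mask = np.isclose(sub_t, ref_tmax)
        if not ref_mask.any():
            raise ValueError(f"reference tmax {ref_tmax} not in grid "
                             f"(precip={precip})")
        ref = draws[pos[ref_mask][0]]                  # (D,)
        pct = 100.0 * (draws[pos] - ref[None, :]) / ref[None, :]
        pct_med[pos] = np.median(pct, axis=1)
        pct_lo[pos] = np.percentile(pct, 2.5, axis=1)
        pct_hi[pos] = np.percentile(pct, 97.5, axis=1)
    out["pct_change_median"] = pct_med
    out["pct_change_lo"] = pct_lo
    out["pct_change_hi"] = pct_hi
    out.attrs["growth_draws"] = draws
    return out


def cohort_benefit(pred_modern: pd.DataFrame,
                   pred_past: pd.DataFrame) -> pd.DataFrame:
    """Percent growth difference, modern vs past class, per grid point.

    Both tables must come from :func:`posterior_predict` on the same
    (tmax, precip) grid. Draws are paired by index, which is exact when
    the two classes come from one joint fit (they share posterior draws);
    the pairing mode is recorded in the output attrs.
    """
    for col in ("tmax", "precip"):
        if not np.array_equal(pred_modern[col].to_numpy(),
                              pred_past[col].to_numpy()):
            raise ValueError("prediction grids are misaligned")
    dm = pred_modern.attrs.get("growth_draws")
    dp = pred_past.attrs.get("growth_draws")
    if dm is None or dp is None or dm.shape != dp.shape:
        raise ValueError("aligned per-draw growth required from both tables")
    pct = 100.0 * (dm - dp) / dp
    out = pred_modern[["tmax", "precip"]].copy()
    out.attrs = {}
    out["benefit_median"] = np.median(pct, axis=1)
    out["benefit_lo"] = np.percentile(pct, 2.5, axis=1)
    out["benefit_hi"] = np.percentile(pct, 97.5, axis=1)
    out.attrs["pairing"] = "joint-fit draw pairing"
    return out


DEFAULT_PERIODS = ((2025, 2049), (2050, 2075), (2075, 2099))


def summarize_scenarios(scenarios: pd.DataFrame,
                        periods=DEFAULT_PERIODS,
                        historical_range: dict | None = None) -> pd.DataFrame:
    """Summarize a climate-scenario table over periods and RCPs.

    ``scenarios`` columns: model, rcp, year, june_tmax, precip. Periods
    are inclusive of both endpoint years as labelled; a year on a shared
    boundary (2075) counts toward the later period only (convention
    recorded in the output attrs). Per period x rcp the mean/min/max of
    both variables across models and years is reported; empty periods are
    omitted with a warning.

    ``historical_range`` (e.g. {"june_tmax": (21, 31), "precip":
    (372, 975)}) flags period/rcp cells whose extremes leave the
    historical covariate space.
    """
    starts = sorted(p[0] for p in periods)
    rows = []
    for lo, hi in periods:
        later = [s for s in starts if lo < s <= hi]
        eff_hi = min(hi, min(later) - 1) if later else hi
        sub = scenarios[(scenarios["year"] >= lo) & (scenarios["year"] <= eff_hi)]
        if sub.empty:
            logger.warning("period %d-%d: no scenario rows, omitted", lo, hi)
            continue
        for rcp, grp in sub.groupby("rcp"):
            rec = {"period": f"{lo}-{hi}", "rcp": rcp, "n": len(grp)}
            for var in ("june_tmax", "precip"):
                rec[f"{var}_mean"] = float(grp[var].mean())
                rec[f"{var}_min"] = float(grp[var].min())
                rec[f"{var}_max"] = float(grp[var].max())
                if historical_range and var in historical_range:
                    lo_h, hi_h = historical_range[var]
                    rec[f"{var}_outside_historical"] = bool(
                        rec[f"{var}_min"] < lo_h or rec[f"{var}_max"] > hi_h)
            rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["boundary_convention"] = ("years on a shared period boundary "
                                        "count toward the later period")
    return out


def plot_growth_curves(pred_tables: list[pd.DataFrame], path: str) -> None:
    """Growth-vs-temperature curves with credible bands, one line per
    precipitation level per class (media output, not a modelling step)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for pred in pred_tables:
        for precip, grp in pred.groupby("precip"):
            grp = grp.sort_values("tmax")
            label = f"{grp['group'].iloc[0]}, {precip:.0f} mm"
            line, = ax.plot(grp["tmax"], grp["growth_median"], label=label)
            ax.fill_between(grp["tmax"], grp["growth_lo"], grp["growth_hi"],
                            alpha=0.15, color=line.get_color())
    ax.set_xlabel("June maximum temperature (degC)")
    ax.set_ylabel("predicted ring width (mm/yr)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
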