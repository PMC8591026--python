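"""Carbon-isotope physiology and the hierarchical iWUE / delta13C models.

Latewood alpha-cellulose delta13C (permil VPDB) records the leaf-internal
CO2 concentration during assimilation. Discrimination against 13C is

    Delta13C = (d13C_atm - d13C_plant) / (1 + d13C_plant/1000)
             = a + (b - a) * ci/ca

with a = 4.4 permil (diffusion) and b = 27 permil (Rubisco carboxylation),
and intrinsic water-use efficiency follows as

    iWUE = A/gs = (ca - ci)/1.6 = ca * (b - Delta13C) / (1.6 * (b - a)).

Raw series are first corrected for the Suess effect (the industrial-era
decline of atmospheric d13C) by subtracting the departure of d13C_atm from
a pre-industrial reference (-6.4 permil), so values are comparable across
centuries.

Baseline (cohort-intercept) differences in iWUE and delta13C, after
adjusting for climate and tree size, estimate the physiological response
to rising atmospheric CO2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ringwue._sampling import truncated_normal, inverse_gamma, mvn_from_precision
from ringwue.growth_model import (
    MU_BOUND, IG_SHAPE, IG_RATE, RHAT_THRESHOLD,
    PosteriorSamples, SamplerSettings, gelman_rubin,
)

logger = logging.getLogger(__name__)

SUESS_REFERENCE = -6.4  # permil; pre-industrial atmospheric d13C

ISO_COVARIATES = ("precip", "tmax", "dbh")
_ISO_COLUMNS = {"precip": "precip_scaled", "tmax": "tmax_scaled",
                "dbh": "dbh_scaled"}


@dataclass(frozen=True)
class FractionationConstants:
    a: float = 4.4      # diffusion fractionation, permil
    b: float = 27.0     # Rubisco carboxylation fractionation, permil
    k_diff: float = 1.6  # CO2/H2O diffusivity ratio, unitless

    def __post_init__(self) -> None:
        if not (self.b > self.a > 0 and self.k_diff > 0):
            raise ValueError("require b > a > 0 and k_diff > 0")


DEFAULT_CONSTANTS = FractionationConstants()


# ---------------------------------------------------------------------------
# point physiology
# ---------------------------------------------------------------------------

def suess_correct(d13c_raw, year, atm: pd.DataFrame,
                  ref_d13c_atm: float = SUESS_REFERENCE):
    """Remove the atmospheric d13C depletion trend from plant d13C.

    corrected = raw - (d13c_atm(year) - ref). ``atm`` has columns
    year, co2_ppm, d13c_atm; every requested year must be covered.
    """
    atm_by_year = atm.set_index("year")["d13c_atm"]
    year = np.asarray(year)
    missing = np.setdiff1d(np.unique(year), atm_by_year.index.to_numpy())
    if missing.size:
        raise KeyError(f"atmosphere record does not cover year(s) {missing}")
    shift = atm_by_year.loc[np.ravel(year)].to_numpy().reshape(np.shape(year))
    return d13c_raw - (shift - ref_d13c_atm)


def discrimination(d13c_atm, d13c_plant):
    """Delta13C (permil) from atmospheric and plant d13C."""
    d13c_plant = np.asarray(d13c_plant, dtype=float)
    denom = 1.0 + d13c_plant / 1000.0
    if np.any(denom <= 0):
        raise ValueError("d13c_plant must exceed -1000 permil")
    return (d13c_atm - d13c_plant) / denom


def plant_d13c(d13c_atm, big_delta):
    """Invert :func:`discrimination`: plant d13C from Delta13C."""
    return (np.asarray(d13c_atm, float) - np.asarray(big_delta, float)) \
        / (1.0 + np.asarray(big_delta, float) / 1000.0)


def ci_over_ca(big_delta, consts: FractionationConstants = DEFAULT_CONSTANTS):
    """Leaf-internal to ambient CO2 ratio from discrimination.

    Values outside [0, 1] are physiologically invalid; they are returned
    (never silently clipped) and flagged by :func:`derive_isotope_table`.
    """
    return (np.asarray(big_delta, float) - consts.a) / (consts.b - consts.a)


def delta_from_ci_ratio(ratio, consts: FractionationConstants = DEFAULT_CONSTANTS):
    """Discrimination from ci/ca (the linear leaf-model identity)."""
    return consts.a + (consts.b - consts.a) * np.asarray(ratio, float)


def iwue(ca, big_delta, consts: FractionationConstants = DEFAULT_CONSTANTS):
    """Intrinsic water-use efficiency (umol CO2 / mol H2O).

    Computed as ca*(b - Delta)/(k_diff*(b - a)); identical algebraically to
    (ca - ci)/k_diff with ci = ca * ci_over_ca(Delta). Both routes are
    asserted equal in the test suite.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("ca must be positive")
    return ca * (consts.b - np.asarray(big_delta, float)) \
        / (consts.k_diff * (consts.b - consts.a))


def iwue_via_ci(ca, big_delta, consts: FractionationConstants = DEFAULT_CONSTANTS):
    """The (ca - ci)/k_diff route; equals :func:`iwue` exactly."""
    ca = np.asarray(ca, dtype=float)
    ci = ca * ci_over_ca(big_delta, consts)
    return (ca - ci) / consts.k_diff


def delta_from_iwue(ca, w, consts: FractionationConstants = DEFAULT_CONSTANTS):
    """Invert :func:`iwue`: discrimination implied by an iWUE value."""
    return consts.b - np.asarray(w, float) * consts.k_diff \
        * (consts.b - consts.a) / np.asarray(ca, float)


def derive_isotope_table(obs: pd.DataFrame, atm: pd.DataFrame,
                         consts: FractionationConstants = DEFAULT_CONSTANTS,
                         ref_d13c_atm: float = SUESS_REFERENCE) -> pd.DataFrame:
    """Add corrected d13C, Delta13C, ci and iWUE columns to a measurement
    table (tree_id, site_id, year, d13c_raw, ...).

    Rows whose discrimination falls outside [a, b] are physiologically
    implausible; they are flagged (column ``delta_valid``) but retained,
    since dropping them would bias cohort contrasts.
    """
    out = obs.copy()
    atm_idx = atm.set_index("year")
    years = out["year"].to_numpy()
    d13c_atm = atm_idx["d13c_atm"].loc[years].to_numpy()
    ca = atm_idx["co2_ppm"].loc[years].to_numpy()
    out["d13c_corrected"] = suess_correct(out["d13c_raw"].to_numpy(), years,
                                          atm, ref_d13c_atm)
    # discrimination uses the raw (uncorrected) plant value with that
    # year's atmospheric d13C: the Suess trend cancels inside Delta13C
    out["big_delta"] = discrimination(d13c_atm, out["d13c_raw"].to_numpy())
    out["ci"] = ca * ci_over_ca(out["big_delta"].to_numpy(), consts)
    out["iwue"] = iwue(ca, out["big_delta"].to_numpy(), consts)
    out["delta_valid"] = out["big_delta"].between(consts.a, consts.b)
    n_bad = int((~out["delta_valid"]).sum())
    if n_bad:
        logger.warning("%d rows with discrimination outside [%.1f, %.1f] "
                       "(flagged, retained)", n_bad, consts.a, consts.b)
    return out


# ---------------------------------------------------------------------------
# hierarchical isotope model
# ---------------------------------------------------------------------------

def _iso_gibbs_chain(y, X, group_idx, C, K, settings, rng) -> np.ndarray:
    """Gibbs chain for y_i ~ N(alpha_c + x_i . beta_c, s2p) with per-class
    intercepts and slopes, uniform hyper-means and IG variances.

    Operates on the standardized response scale; back-transformation to
    natural units happens in the caller.
    """
    rows = [np.flatnonzero(group_idx == c) for c in range(C)]
    Xg = [X[r] for r in rows]
    XtX = [x.T @ x for x in Xg]
    n_c = np.array([len(r) for r in rows])
    n = len(y)

    alpha = np.zeros(C)
    beta = np.zeros((K, C))
    mu_alpha = 0.0
    mu_beta = np.zeros(K)
    s2p = 1.0
    s2a = np.ones(C)
    s2b = np.ones((K, C))

    n_ret = settings.retained_per_chain
    out = np.empty((n_ret, C + K * C + 1 + K + 1 + C + K * C))
    kept = 0
    for it in range(settings.iterations):
        for c in range(C):
            r = y[rows[c]] - alpha[c]
            prec = XtX[c] / s2p + np.diag(1.0 / s2b[:, c])
            b = Xg[c].T @ r / s2p + mu_beta / s2b[:, c]
            beta[:, c] = mvn_from_precision(b, prec, rng)

        for c in range(C):
            r = y[rows[c]] - Xg[c] @ beta[:, c]
            prec = n_c[c] / s2p + 1.0 / s2a[c]
            mean = (r.sum() / s2p + mu_alpha / s2a[c]) / prec
            alpha[c] = mean + rng.standard_normal() / np.sqrt(prec)

        w = 1.0 / s2a
        mu_alpha = truncated_normal(float(np.sum(alpha * w) / np.sum(w)),
                                    float(1.0 / np.sqrt(np.sum(w))),
                                    -MU_BOUND, MU_BOUND, rng)
        for k in range(K):
            wk = 1.0 / s2b[k]
            mu_beta[k] = truncated_normal(
                float(np.sum(beta[k] * wk) / np.sum(wk)),
                float(1.0 / np.sqrt(np.sum(wk))), -MU_BOUND, MU_BOUND, rng)

        err = y - alpha[group_idx] - np.einsum("nk,kn->n", X, beta[:, group_idx])
        s2p = inverse_gamma(IG_SHAPE + n / 2.0,
                            IG_RATE + float(err @ err) / 2.0, rng)
        for c in range(C):
            s2a[c] = inverse_gamma(IG_SHAPE + 0.5,
                                   IG_RATE + (alpha[c] - mu_alpha) ** 2 / 2.0,
                                   rng)
        for k in range(K):
            for c in range(C):
                s2b[k, c] = inverse_gamma(
                    IG_SHAPE + 0.5,
                    IG_RATE + (beta[k, c] - mu_beta[k]) ** 2 / 2.0, rng)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 \
                and kept < n_ret:
            out[kept] = np.concatenate([alpha, beta.ravel(), [mu_alpha],
                                        mu_beta, [s2p], s2a, s2b.ravel()])
            kept += 1
    return out


def sample_isotope_posterior(obs: pd.DataFrame, response: str = "iwue",
                             grouping: str = "cohort_structure",
                             settings: SamplerSettings | None = None
                             ) -> PosteriorSamples:
    """Fit the hierarchical isotope model for iWUE or (corrected) d13C.

    ``obs`` must carry the response column (``iwue`` or
    ``d13c_corrected``/``d13c`` for the isotope-ratio fit), a ``group``
    column, and the scaled covariates precip_scaled, tmax_scaled,
    dbh_scaled.

    The response is centred and scaled internally so the Uniform(-2, 2)
    hyper-mean priors are sensible for any response units (raw iWUE means
    sit near 100 umol/mol); all location draws and the process variance
    are back-transformed to natural units before being returned, and the
    transformation is recorded in ``meta["response_transform"]``.
    """
    settings = settings or SamplerSettings()
    col = {"iwue": "iwue", "d13c": "d13c_corrected"}.get(response, response)
    if col not in obs.columns:
        raise ValueError(f"response column {col!r} not in obs")
    if "group" not in obs.columns:
        raise ValueError("obs must carry a 'group' column")
    groups = sorted(obs["group"].unique())
    counts = obs["group"].value_counts()
    if (counts < 3).any():
        raise ValueError("each class needs >= 3 observations")
    group_idx = obs["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    X = obs[[_ISO_COLUMNS[k] for k in ISO_COVARIATES]].to_numpy(float)
    y_raw = obs[col].to_numpy(float)
    m_y, s_y = float(np.mean(y_raw)), float(np.std(y_raw, ddof=1))
    y = (y_raw - m_y) / s_y
    C, K = len(groups), X.shape[1]

    chains = []
    for ch in range(settings.chains):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=settings.seed, spawn_key=(ch,)))
        chains.append(_iso_gibbs_chain(y, X, group_idx, C, K, settings, rng))
    draws = np.stack(chains)

    # back-transform to natural units: locations y = m + s*z, scales *s,
    # variances *s^2
    P = draws.shape[2]
    scale_vec = np.full(P, s_y)
    shift_vec = np.zeros(P)
    # alpha block and mu_alpha get the mean shift
    shift_vec[:C] = m_y
    shift_vec[C + K * C] = m_y
    # variance block scales with s^2
    var_start = C + K * C + 1 + K
    scale_vec[var_start:] = s_y ** 2
    draws = draws * scale_vec + shift_vec

    names = ([f"alpha[{g}]" for g in groups]
             + [f"beta_{k}[{g}]" for k in ISO_COVARIATES for g in groups]
             + ["mu_alpha"] + [f"mu_beta_{k}" for k in ISO_COVARIATES]
             + ["sigma2_p"] + [f"sigma2_alpha[{g}]" for g in groups]
             + [f"sigma2_beta_{k}[{g}]" for k in ISO_COVARIATES for g in groups])
    samples = PosteriorSamples(draws, names, settings, meta={
        "groups": groups, "covariates": list(ISO_COVARIATES),
        "response": response, "grouping": grouping, "n_obs": len(y),
        "model": "isotope",
        "response_transform": {"mean": m_y, "sd": s_y}})
    rhat = gelman_rubin(samples)
    converged = bool((rhat.dropna() < RHAT_THRESHOLD).all())
    samples.meta["converged"] = converged
    samples.meta["max_rhat"] = float(rhat.max())
    if not converged:
        logger.warning("isotope MCMC NOT CONVERGED: max rhat %.3f",
                       rhat.max())
    return samples


def baseline_contrast(samples: PosteriorSamples,
                      group_pair: tuple[str, str]) -> dict:
    """Cohort contrast of baseline intercepts, e.g.
    ("Past-Forest", "Modern-Forest").

    For an iWUE fit reports the per-draw percent change
    100*(alpha_modern - alpha_past)/alpha_past; for d13C (or whenever the
    reference baseline draws cross zero, where a percent change is
    meaningless) the absolute difference in natural units. Posterior mean
    and the equal-tailed 95% credible interval are returned.
    """
    past, modern = group_pair
    a_past = samples.flat(f"alpha[{past}]")
    a_mod = samples.flat(f"alpha[{modern}]")
    diff = a_mod - a_past
    out = {"pair": group_pair,
           "abs_diff_mean": float(diff.mean()),
           "abs_diff_ci": (float(np.percentile(diff, 2.5)),
                           float(np.percentile(diff, 97.5)))}
    wants_percent = samples.meta.get("response") == "iwue"
    if wants_percent:
        if np.any(a_past <= 0):
            logger.warning("reference baseline draws cross zero; "
                           "percent contrast unavailable, reporting "
                           "absolute difference only")
            out["percent_mean"] = None
        else:
            pct = 100.0 * diff / a_past
            out["percent_mean"] = float(pct.mean())
            out["percent_ci"] = (float(np.percentile(pct, 2.5)),
                                 float(np.percentile(pct, 97.5)))
    return out
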