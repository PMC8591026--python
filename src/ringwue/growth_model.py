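"""Hierarchical Bayesian model of annual tree-ring growth.

The response is log ring width (ln mm). For observation i of tree t at
site s in class c (cohort, or cohort x stand structure):

    log(growth)_i ~ Normal(g_i, sigma_p^2)
    g_i = alpha_s + b1c * Precip_i + b2c * MaxTemp_i
          + b3c * (MaxTemp x Precip)_i + b4c * lag1_i + b5c * lag2_i
          + b6c * DBH_i

with climate and size covariates z-scored within class, and lag1/lag2 the
previous two years' log growth of the same tree. Priors:

    alpha_s     ~ Normal(mu_alpha, sigma2_alpha)   (site random intercepts)
    beta_kc     ~ Normal(mu_beta_k, sigma2_beta_kc) (class random slopes)
    mu_alpha, mu_beta_k ~ Uniform(-2, 2)
    sigma2_p, sigma2_alpha, sigma2_beta_kc ~ InvGamma(0.001, 0.001)

Every full conditional is conjugate (normal or inverse-gamma; the
hyper-means are normals truncated to [-2, 2]), so the posterior is sampled
by a plain Gibbs sampler. This mixes fast on linear-normal hierarchies, so
the default desk-scale settings (3 chains x 4000 iterations, thin 2) are
far smaller than what black-box MCMC would need.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from ringwue._sampling import truncated_normal, inverse_gamma, mvn_from_precision

logger = logging.getLogger(__name__)

MU_BOUND = 2.0          # uniform hyper-prior support [-2, 2]
IG_SHAPE = 0.001        # inverse-gamma prior shape
IG_RATE = 0.001         # inverse-gamma prior rate
RHAT_THRESHOLD = 1.1

#: slope order: covariate name -> column of the design matrix
COVARIATES = ("precip", "tmax", "interaction", "lag1", "lag2", "dbh")
_COLUMNS = {"precip": "precip_scaled", "tmax": "tmax_scaled",
            "interaction": "interaction", "lag1": "lag1_log_growth",
            "lag2": "lag2_log_growth", "dbh": "dbh_scaled"}


@dataclass
class ModelSpec:
    """Which random-effect classes and covariates the fit uses.

    ``covariate_list`` restricts the slopes to a subset of
    :data:`COVARIATES` (an empty tuple gives the intercept-only model used
    for conjugate sanity checks); by default all six covariates enter,
    minus the interaction when ``include_interaction`` is off.
    """

    grouping: str = "cohort_structure"   # "cohort" (C=2) or "cohort_structure" (C=4)
    include_interaction: bool = True
    covariate_list: tuple[str, ...] | None = None

    @property
    def covariates(self) -> tuple[str, ...]:
        if self.covariate_list is not None:
            unknown = set(self.covariate_list) - set(COVARIATES)
            if unknown:
                raise ValueError(f"unknown covariates {sorted(unknown)}")
            return tuple(self.covariate_list)
        if self.include_interaction:
            return COVARIATES
        return tuple(c for c in COVARIATES if c != "interaction")


@dataclass
class SamplerSettings:
    iterations: int = 4000
    burn_in: int = 2000
    thin: int = 2
    chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class GrowthParams:
    """One point in parameter space (e.g. one posterior draw)."""

    sites: list[str]
    groups: list[str]
    covariates: tuple[str, ...]
    alpha_s: np.ndarray          # (S,)
    beta: np.ndarray             # (K, C)
    mu_alpha: float = 0.0
    mu_beta: np.ndarray | None = None    # (K,)
    sigma2_p: float = 1.0
    sigma2_alpha: float = 1.0
    sigma2_beta: np.ndarray | None = None  # (K, C)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws: chains x iterations x parameters."""

    draws: np.ndarray            # (chains, n_retained, P)
    names: list[str]
    settings: SamplerSettings
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.names)}

    def param(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, n_retained)."""
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.param(name).reshape(-1)

    def posterior_mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=(0, 1)), index=self.names)

    def summary(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        return pd.DataFrame({
            "mean": flat.mean(0),
            "sd": flat.std(0, ddof=1),
            "q2.5": np.percentile(flat, 2.5, axis=0),
            "q50": np.percentile(flat, 50, axis=0),
            "q97.5": np.percentile(flat, 97.5, axis=0),
        }, index=self.names)

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        c, n, p = self.draws.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(c), n * p),
            "iteration": np.tile(np.repeat(np.arange(n), p), c),
            "parameter": np.tile(self.names, c * n),
            "value": self.draws.reshape(-1),
        })


@dataclass
class FitDiagnostics:
    rhat: pd.Series
    dic: float
    r2: float | None
    mspe: float | None
    bias: float | None
    converged: bool


# ---------------------------------------------------------------------------
# deterministic pieces
# ---------------------------------------------------------------------------

def _design(obs: pd.DataFrame, spec: ModelSpec):
    """Response vector, design matrix and index arrays from a scaled table."""
    needed = ["group"] + [_COLUMNS[c] for c in spec.covariates]
    missing = [c for c in needed if c not in obs.columns]
    if missing:
        raise ValueError(f"obs lacks columns {missing}; run assign_groups and "
                         "scale_covariates first")
    sites = sorted(obs["site_id"].unique())
    groups = sorted(obs["group"].unique())
    site_idx = obs["site_id"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    group_idx = obs["group"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    X = obs[[_COLUMNS[c] for c in spec.covariates]].to_numpy(float)
    y = obs["log_growth"].to_numpy(float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite covariate or response values")
    return y, X, site_idx, group_idx, sites, groups


def linear_predictor(params: GrowthParams, obs: pd.DataFrame) -> np.ndarray:
    """Mean log growth g for each observation row under ``params``."""
    spec = ModelSpec(include_interaction="interaction" in params.covariates)
    site_map = {s: i for i, s in enumerate(params.sites)}
    group_map = {g: i for i, g in enumerate(params.groups)}
    try:
        s_idx = obs["site_id"].map(site_map).to_numpy(float)
        g_idx = obs["group"].map(group_map).to_numpy(float)
    except KeyError as exc:
        raise KeyError(f"unknown site or group: {exc}") from exc
    if np.isnan(s_idx).any() or np.isnan(g_idx).any():
        raise KeyError("observation references a site or group unknown to params")
    s_idx = s_idx.astype(int)
    g_idx = g_idx.astype(int)
    X = obs[[_COLUMNS[c] for c in params.covariates]].to_numpy(float)
    B = params.beta[:, g_idx]               # (K, n)
    return params.alpha_s[s_idx] + np.einsum("nk,kn->n", X, B)


def log_likelihood(params: GrowthParams, obs: pd.DataFrame) -> float:
    """Sum of normal log densities of log growth at the linear predictor."""
    if params.sigma2_p <= 0:
        raise ValueError("sigma2_p must be positive")
    g = linear_predictor(params, obs)
    ll = norm.logpdf(obs["log_growth"].to_numpy(float), loc=g,
                     scale=np.sqrt(params.sigma2_p))
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite log likelihood at row {bad}")
    return float(ll.sum())


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _gibbs_chain(y, X, site_idx, group_idx, S, C, K, settings: SamplerSettings,
                 rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    groups_rows = [np.flatnonzero(group_idx == c) for c in range(C)]
    Xg = [X[r] for r in groups_rows]
    XtX = [x.T @ x for x in Xg]
    n_site = np.bincount(site_idx, minlength=S)

    # initial state: data-scale guesses, deterministic
    alpha = np.full(S, float(np.mean(y)))
    beta = np.zeros((K, C))
    mu_alpha = float(np.clip(np.mean(y), -MU_BOUND, MU_BOUND))
    mu_beta = np.zeros(K)
    s2p, s2a = 1.0, 1.0
    s2b = np.ones((K, C))

    n_ret = settings.retained_per_chain
    out = np.empty((n_ret, S + K * C + 1 + K + 2 + K * C))
    kept = 0

    for it in range(settings.iterations):
        # --- beta blocks, one multivariate normal per class c
        if K:
            r_alpha = y - alpha[site_idx]
            for c in range(C):
                rows = groups_rows[c]
                prec = XtX[c] / s2p + np.diag(1.0 / s2b[:, c])
                b = Xg[c].T @ r_alpha[rows] / s2p + mu_beta / s2b[:, c]
                beta[:, c] = mvn_from_precision(b, prec, rng)

        # --- site intercepts
        xb = np.einsum("nk,kn->n", X, beta[:, group_idx])
        resid = y - xb
        site_sum = np.bincount(site_idx, weights=resid, minlength=S)
        prec_a = n_site / s2p + 1.0 / s2a
        mean_a = (site_sum / s2p + mu_alpha / s2a) / prec_a
        alpha = mean_a + rng.standard_normal(S) / np.sqrt(prec_a)

        # --- hyper-means, truncated to the uniform support
        mu_alpha = truncated_normal(float(np.mean(alpha)),
                                    float(np.sqrt(s2a / S)),
                                    -MU_BOUND, MU_BOUND, rng)
        for k in range(K):
            w = 1.0 / s2b[k]
            mu_beta[k] = truncated_normal(
                float(np.sum(beta[k] * w) / np.sum(w)),
                float(1.0 / np.sqrt(np.sum(w))), -MU_BOUND, MU_BOUND, rng)

        # --- variances
        err = resid - alpha[site_idx]
        s2p = inverse_gamma(IG_SHAPE + n / 2.0,
                            IG_RATE + float(err @ err) / 2.0, rng)
        dev_a = alpha - mu_alpha
        s2a = inverse_gamma(IG_SHAPE + S / 2.0,
                            IG_RATE + float(dev_a @ dev_a) / 2.0, rng)
        dev_b = (beta - mu_beta[:, None]) ** 2
        for k in range(K):
            for c in range(C):
                s2b[k, c] = inverse_gamma(IG_SHAPE + 0.5,
                                          IG_RATE + dev_b[k, c] / 2.0, rng)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0 \
                and kept < n_ret:
            out[kept] = np.concatenate([
                alpha, beta.ravel(), [mu_alpha], mu_beta,
                [s2p, s2a], s2b.ravel()])
            kept += 1
    return out


def _param_names(sites, groups, covariates) -> list[str]:
    names = [f"alpha[{s}]" for s in sites]
    names += [f"beta_{k}[{g}]" for k in covariates for g in groups]
    names += ["mu_alpha"] + [f"mu_beta_{k}" for k in covariates]
    names += ["sigma2_p", "sigma2_alpha"]
    names += [f"sigma2_beta_{k}[{g}]" for k in covariates for g in groups]
    return names


def sample_posterior(obs: pd.DataFrame, spec: ModelSpec | None = None,
                     settings: SamplerSettings | None = None
                     ) -> PosteriorSamples:
    """Fit the growth model by Gibbs sampling.

    ``obs`` must be scaled and carry ``group`` (see
    :func:`ringwue.io_ingest.assign_groups` and
    :func:`ringwue.climate_prep.scale_covariates`). Chains are seeded from
    independent streams spawned from ``settings.seed``, so runs are exactly
    reproducible. If any parameter's Gelman-Rubin statistic exceeds 1.1
    the result carries ``meta["converged"] = False`` and a warning is
    logged -- never a silent failure.
    """
    spec = spec or ModelSpec()
    settings = settings or SamplerSettings()
    y, X, site_idx, group_idx, sites, groups = _design(obs, spec)
    S, C, K = len(sites), len(groups), X.shape[1]
    counts = np.bincount(group_idx, minlength=C)
    if np.any(counts < 2):
        raise ValueError("each class needs >= 2 observations")

    chains = []
    for ch in range(settings.chains):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=settings.seed, spawn_key=(ch,)))
        chains.append(_gibbs_chain(y, X, site_idx, group_idx, S, C, K,
                                   settings, rng))
    draws = np.stack(chains)
    names = _param_names(sites, groups, spec.covariates)
    samples = PosteriorSamples(draws, names, settings, meta={
        "sites": sites, "groups": groups, "covariates": list(spec.covariates),
        "grouping": spec.grouping, "n_obs": len(y), "model": "growth"})
    rhat = gelman_rubin(samples)
    converged = bool((rhat.dropna() < RHAT_THRESHOLD).all())
    samples.meta["converged"] = converged
    samples.meta["max_rhat"] = float(rhat.max())
    if not converged:
        logger.warning("MCMC NOT CONVERGED: max rhat %.3f > %.2f",
                       rhat.max(), RHAT_THRESHOLD)
    return samples


def params_at(samples: PosteriorSamples, reducer=np.mean) -> GrowthParams:
    """Point parameters (default: posterior means) as a GrowthParams."""
    m = samples.meta
    sites, groups = m["sites"], m["groups"]
    covs = tuple(m["covariates"])
    val = lambda name: float(reducer(samples.flat(name)))
    beta = np.array([[val(f"beta_{k}[{g}]") for g in groups] for k in covs])
    return GrowthParams(
        sites=sites, groups=groups, covariates=covs,
        alpha_s=np.array([val(f"alpha[{s}]") for s in sites]),
        beta=beta,
        mu_alpha=val("mu_alpha"),
        mu_beta=np.array([val(f"mu_beta_{k}") for k in covs]),
        sigma2_p=val("sigma2_p"),
        sigma2_alpha=val("sigma2_alpha"),
        sigma2_beta=np.array([[val(f"sigma2_beta_{k}[{g}]") for g in groups]
                              for k in covs]))


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """Potential scale reduction factor per parameter.

    Classic between/within form: with m chains of length n, W the mean
    within-chain variance and B/n the between-chain variance of chain
    means, rhat = sqrt(((n-1)/n W + B/n) / W). Constant parameters
    (e.g. degenerate draws) give NaN.
    """
    m, n, _ = samples.draws.shape
    if m < 2:
        raise ValueError("gelman_rubin requires >= 2 chains")
    if n < 10:
        raise ValueError("gelman_rubin requires >= 10 retained draws per chain")
    chain_means = samples.draws.mean(axis=1)            # (m, P)
    chain_vars = samples.draws.var(axis=1, ddof=1)      # (m, P)
    W = chain_vars.mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n - 1) / n * W + B_over_n
        rhat = np.sqrt(var_hat / W)
    return pd.Series(rhat, index=samples.names, name="rhat")


def _deviance(params: GrowthParams, obs: pd.DataFrame) -> float:
    return -2.0 * log_likelihood(params, obs)


def model_metrics(samples: PosteriorSamples, train: pd.DataFrame,
                  test: pd.DataFrame | None) -> FitDiagnostics:
    """DIC on the training data plus held-out prediction metrics.

    DIC = Dbar + pD with pD = Dbar - D(theta_bar) (posterior-mean plug-in).
    R^2, MSPE and bias compare posterior-mean predicted log growth with
    held-out observed log growth; R^2 = 1 - SS_res/SS_tot, so a constant
    prediction at the held-out mean scores 0.
    """
    rhat = gelman_rubin(samples)
    mean_params = params_at(samples)

    # mean deviance over a thinned subset of draws (deviance is linear in
    # the per-draw log likelihood; 200 draws give ample precision)
    c, n, _ = samples.draws.shape
    step = max(1, (c * n) // 200)
    devs = []
    for idx in range(0, c * n, step):
        ch, it = divmod(idx, n)
        one = PosteriorSamples(samples.draws[ch:ch + 1, it:it + 1, :],
                               samples.names, samples.settings, samples.meta)
        devs.append(_deviance(params_at(one), train))
    dbar = float(np.mean(devs))
    pd_eff = dbar - _deviance(mean_params, train)
    dic = dbar + pd_eff

    r2 = mspe = bias = None
    if test is not None and len(test):
        pred = linear_predictor(mean_params, test)
        y = test["log_growth"].to_numpy(float)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        mspe = float(np.mean((pred - y) ** 2))
        bias = float(np.mean(pred - y))
    else:
        logger.warning("empty test set: R2/MSPE/bias undefined")
    return FitDiagnostics(rhat=rhat, dic=dic, r2=r2, mspe=mspe, bias=bias,
                          converged=bool(samples.meta.get("converged", True)))


def compare_models(obs_train: pd.DataFrame, obs_test: pd.DataFrame,
                   specs: list[ModelSpec],
                   settings: SamplerSettings | None = None) -> pd.DataFrame:
    """Fit several specs on the same split and tabulate their diagnostics.

    The lowest-DIC spec is flagged; a failed fit marks its row and leaves
    the others unaffected.
    """
    from ringwue.io_ingest import assign_groups
    from ringwue.climate_prep import scale_covariates

    rows = []
    for spec in specs:
        label = f"{spec.grouping}{'+int' if spec.include_interaction else ''}"
        try:
            tr = assign_groups(obs_train, spec.grouping)
            te = assign_groups(obs_test, spec.grouping)
            tr, params = scale_covariates(tr)
            te, _ = scale_covariates(te, params)
            samples = sample_posterior(tr, spec, settings)
            d = model_metrics(samples, tr, te)
            rows.append({"model": label, "dic": d.dic, "r2": d.r2,
                         "mspe": d.mspe, "bias": d.bias,
                         "max_rhat": float(d.rhat.max()),
                         "converged": d.converged, "failed": False})
        except Exception as exc:  # noqa: BLE001 - isolate per-spec failures
            logger.error("fit failed for %s: %s", label, exc)
            rows.append({"model": label, "failed": True})
    table = pd.DataFrame(rows)
    if "dic" in table.columns and table["dic"].notna().any():
        table["best_dic"] = table["dic"] == table["dic"].min()
    return table
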