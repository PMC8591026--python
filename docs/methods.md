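# Methods

This note documents the statistical models, the numerical choices behind
the samplers, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the design was genuinely
open.

## Growth model

Annual log ring width (ln mm) of tree *t* at site *s* in class *c* is
modelled as

    log(growth)_i ~ Normal(g_i, sigma_p^2)
    g_i = alpha_s + b1c Precip_i + b2c MaxTemp_i + b3c (MaxTemp x Precip)_i
          + b4c lag1_i + b5c lag2_i + b6c DBH_i

* **Classes.** Either the two establishment cohorts (Past: innermost
  ring before 1895; Modern: 1895–1950, boundary years inclusive in
  Modern), or the four cohort × stand-structure combinations. Cohorts are
  compared on disjoint windows — Past trees contribute 1895–1949 rings,
  Modern trees 1950–2015 — so each class is observed at comparable ages.
* **Covariates.** Water-year precipitation (Oct–Sep total, mm), June
  maximum temperature (°C) and reconstructed diameter (cm) are z-scored
  within class; the interaction column is the product of the two climate
  z-scores. The two lag terms are the same tree's log growth one and two
  years earlier, entered unscaled (they live on the response scale).
* **Priors.** alpha_s ~ N(mu_alpha, sigma2_alpha); b_kc ~ N(mu_bk,
  sigma2_bkc) with one variance per slope per class; mu's ~ Uniform(−2, 2)
  (log-mm effects are well inside this range); all variances
  inverse-gamma(0.001, 0.001) in the shape/rate convention.

### Sampler

Every full conditional is conjugate, so the posterior is drawn by plain
Gibbs: a multivariate-normal block per class for the six slopes,
normal updates for site intercepts, truncated-normal updates for the
hyper-means (exact inverse-CDF sampling on [−2, 2]), and inverse-gamma
updates for all variances. Chains are seeded from independent
`SeedSequence` spawns of one integer seed, so runs are bit-reproducible.

Defaults are 3 chains × 4000 iterations, burn-in 50%, thinning 2.
These are deliberately small: on linear-normal hierarchies the
conjugate Gibbs sampler mixes almost independently (measured lag-1
autocorrelation of intercept draws is below 0.01 on the covariate-free
model), so a few thousand iterations give Monte-Carlo errors far below
posterior spread. The settings are fully configurable for longer runs;
retained draws per chain are floor((iterations − burn-in)/thin).

Convergence is assessed with the classic Gelman–Rubin
potential-scale-reduction factor, rhat = sqrt(((n−1)/n W + B/n)/W) over
chains. A fit with any rhat above 1.1 is returned with a prominent
warning and `meta["converged"] = False`, never silently.

Model comparison uses DIC = D̄ + pD with pD = D̄ − D(θ̄) (posterior-mean
plug-in); D̄ is averaged over an evenly thinned subset of at most 200
retained draws, which bounds its Monte-Carlo error well below
between-model DIC differences. Held-out performance is the R², mean
squared prediction error and mean bias of posterior-mean predicted log
growth against held-out observations; R² = 1 − SSres/SStot, so a
constant prediction at the held-out mean scores exactly zero.

### Degenerate cases

An intercept-only specification (`ModelSpec(covariate_list=())`) is
supported and used to validate the sampler against the flat-mean
normal-inverse-gamma closed form. Supplying covariate columns that are
identically zero instead is rejected by design intent: with no data
contribution, the slope/variance subchain under inverse-gamma(0.001,
0.001) priors is a heavy-tailed random walk and does not represent any
inference a user would want.

## Isotope physiology and model

Raw latewood δ¹³C is corrected for the Suess effect by subtracting the
departure of atmospheric δ¹³C from a pre-industrial reference of
−6.4 ‰ (configurable). Discrimination uses the raw plant value with the
same year's atmospheric δ¹³C (the atmospheric trend cancels inside
Δ¹³C), so corrected δ¹³C matters only for cross-century comparisons of
the isotope ratio itself, and the hierarchical δ¹³C model fits corrected
values by default (switchable).

iWUE is computed as ca(b − Δ)/(1.6(b − a)), algebraically identical to
(ca − ci)/1.6; both routes are implemented and asserted equal to 1e-10.
Rows with Δ¹³C outside [a, b] = [4.4, 27] ‰ are physiologically
implausible; they are flagged and retained (dropping them would bias
cohort contrasts).

The hierarchical isotope model has class intercepts and class slopes on
precipitation, June maximum temperature and DBH, with the same prior
family as the growth model. Because raw iWUE means sit near 100
μmol mol⁻¹, far outside the Uniform(−2, 2) hyper-mean support, the
response is centred and scaled internally; all location draws and the
process variance are back-transformed to natural units before return and
the transformation is recorded in the samples' metadata. Baseline
contrasts report the per-draw percent change of the modern intercept
over the past intercept (iWUE), falling back to absolute differences if
reference draws cross zero, and always for δ¹³C (a percent change of a
‰ value is not meaningful).

## Climate preparation

* Water-year totals are defined only when all 12 contributing months are
  present; the first year of every record therefore drops.
* The drought filter retains, within each (site, cohort) group, the
  years whose June–August mean PDSI lies at or below the group's 0.75
  quantile — i.e. it keeps the drier three quarters and discards the
  wettest quarter, focusing the climate contrast on drought years. The
  quantile uses the linear-interpolation convention. The direction is a
  flag (`keep="wet"` inverts it); groups with fewer than 4 distinct
  years pass through unfiltered with a warning. Note the filter is not
  idempotent: reapplying it recomputes quantiles on the already-filtered
  output and removes more years, as any quantile filter does.
* The train/test split is random but stratified by (site, cohort),
  preserving the hierarchical balance; the mechanism behind the original
  1124/379 split is not documented, so stratified-random is the default
  and the choice and seed are recorded with the output.
* Climate-matched year pairs for isotope sampling come from
  correlation-matrix PCA (standardized 12 precip + 12 tmax + 12 PDSI
  monthly variables) over all candidate years of one site, followed by
  greedy nearest-pair matching in (PC1, PC2) with ties broken by the
  earlier past year. Greedy matching is not globally optimal but is
  transparent and stable; with k = 1 it equals the exhaustive minimum.

## Ingest conventions

* Tucson (.rwl) decadal files: unit conversion follows the end-of-series
  sentinel (999 → 0.01 mm, −9999 → 0.001 mm) with an explicit override
  for dialects without one. Non-consecutive decade rows are a parse
  error naming the line.
* Establishment year is the innermost measured ring year; no pith-offset
  correction is attempted (none is estimable from the inputs).
* Multiple cores of one tree are averaged by year before modelling.
* Diameters are reconstructed backwards from the census DBH by
  subtracting twice each ring width (bark ignored — a constant offset
  absorbed by class scaling), floored at 0.1 cm with a warning. The DBH
  covariate for growth year t is the reconstructed diameter at the end
  of year t−1: the size the tree brings into the growth year, which
  avoids conditioning a year's growth on itself.
* Nonpositive or missing rings are treated as missing: the year itself
  and the two following years (whose lags depend on it) are dropped;
  log(0) never enters the model.

## Posterior prediction

Grids are specified in natural units and scored through the stored class
scaling; lag covariates default to the class mean log growth and DBH to
the class mean diameter. The site intercept is taken at its population
mean mu_alpha, i.e. predictions describe a typical site. Process error
(a per-draw Normal(0, sigma_p^2) shock before exponentiation) is
included by default so bands are full posterior predictive intervals;
without it the bands describe the median ring width only, and are
strictly narrower. Percent-change contrasts versus the 26 °C reference
and modern-vs-past benefits are computed per draw, paired by draw index
(exact when both classes come from one joint fit). Grid points outside
the historical covariate range are flagged, not refused. Scenario
summaries treat period bounds as inclusive as labelled, with a year on a
shared boundary (2075) assigned to the later period.

## Synthetic-data generator

The generator emulates the study conditions, not generic data:

* **Climate.** Nine sites; water-year precipitation means on a
  600–850 mm gradient (inside the study's 577–873 mm envelope, with
  margin so realized long-run means stay inside), June maximum
  temperature means 24.3–26.6 °C, gamma monthly precipitation with a
  summer-peaked seasonal cycle, sinusoidal temperature, AR(1) monthly
  PDSI (persistence 0.7, stationary sd 2).
* **Trees.** The realized design of the study: 54 Past + 49 Modern trees,
  72 in savannas and 31 in forests, allocated round-robin across sites;
  establishment years uniform within each cohort's window.
* **Growth.** Forward simulation of the growth model with generating
  coefficients defaulting to the reported structure–cohort posterior
  means (precipitation 0.111/0.014/0.129/0.029; temperature
  −0.073/−0.054/−0.094/−0.081; lag-1 0.578/0.489/0.513/0.55; lag-2
  0.216/0.387/0.129/0.232 for Past-Savanna/Modern-Savanna/Past-Forest/
  Modern-Forest; interaction 0.064 in Modern-Savanna, 0.03 in
  Modern-Forest, 0 in the past classes where none is reported), process
  sd 0.3, site intercepts N(0.06, 0.03²) — giving stationary mean growth
  near 1.4–1.7 mm/yr. Lags initialize at the deterministic fixed point
  of the lag recursion for the first year (the first two years are
  dropped downstream anyway); configurations with |b4| + |b5| ≥ 1 are
  refused as explosive. The DBH coefficient defaults to −0.05 per sd:
  no value is reported, and a positive coefficient is an unstable
  positive feedback in forward simulation (wider rings → larger diameter
  → wider rings) that diverges over a century, whereas a small negative
  value reproduces the classic decline of ring width with size.
* **Self-consistent scaling.** Climate covariates are z-scored by the
  class statistics of exactly the tree-years the fit will retain, so
  generating and fitted coefficients live on the same scale. The DBH
  statistics depend on the growth being generated, so the generator
  iterates to a fixed point (identical noise streams each pass,
  tolerance 1e-6 cm): the statistics used for generation equal the
  realized ones, removing what would otherwise be a first-order bias in
  the recovered DBH slope.
* **Isotopes.** Per class, 8 trees × 12 years sampled from the cohort
  windows; iWUE drawn from the hierarchical model with baselines
  encoding the reported cohort increases (+12.8% savanna, +21% forest
  over past baselines of 105 and 95 μmol mol⁻¹, process sd 8), then
  inverted through the discrimination identities with each year's CO2
  and δ¹³C_atm so raw values carry the atmospheric trend and exercise
  the Suess correction. Non-physiological draws (Δ outside (0, b)) are
  resampled with a retry cap.
* **Atmosphere.** A smooth synthetic stand-in (ca = 280 +
  120·exp((year − 2015)/50) ppm; δ¹³C_atm declining linearly in the CO2
  excess from −6.4 to −8.4 ‰) with the qualitative shape of the
  observational composites. It is generated by code, not shipped as
  data, and is explicitly not the Keeling/ice-core record.

What the generator does not emulate: spatial correlation of climate
across sites, measurement error in ring widths and δ¹³C beyond the
process terms, missing rings (off by default; injectable), crossdating
error, within-tree circuit variability of multiple cores, pith offsets,
or age-dependent physiology beyond the DBH term. Passing recovery tests
therefore demonstrate that the estimators are correct and well
calibrated under the model's own assumptions at the study's realized
design and effect sizes — not that the model is adequate for any real
stand.

## Problem sizes

The default recovery experiment is the full realized design (103 trees,
≈6200 retained tree-years) fitted with 3 × 4000 Gibbs iterations — about
ten seconds on one CPU — and the isotope experiment is 384 measurements
with the same sampler settings. Unit tests use a reduced 20-tree design.
These sizes were chosen so the posterior standard errors are several
times smaller than the widths of the reported credible intervals being
recovered, which is what makes the recovery checks informative.

## Known limitations

* The Gibbs sampler covers the conjugate prior family only; alternative
  likelihoods (Student-t, hurdle models for locally absent rings) would
  need a Metropolis extension.
* Per-slope-per-class inverse-gamma(0.001, 0.001) variances are weakly
  identified from a single deviation each; they mainly act as adaptive
  shrinkage weights, and their own posteriors should not be
  over-interpreted.
* DIC is reported because it is the convention in this literature;
  WAIC/LOO would be preferable on statistical grounds and can be added
  from the retained per-draw likelihoods.
* The isotope model treats each measurement as independent given its
  class; year-level climate shocks shared across trees are not modelled
  as random effects.
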