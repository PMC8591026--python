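# ringwue

Hierarchical Bayesian analysis of annual tree-ring growth and intrinsic
water-use efficiency (iWUE) across a temperate savanna–forest ecotone.

## The scientific problem

Rising atmospheric CO2 increases plant water-use efficiency, which should
reduce the sensitivity of tree growth to precipitation — yet the expected
growth gains are rarely seen in ring-width records, plausibly because
higher summer temperatures offset them. Disentangling these effects
requires jointly modelling (a) ring-width responses to climate, size and
lagged growth for trees that established under low vs high CO2 ("Past":
innermost ring before 1895; "Modern": 1895–1950), in open savannas vs
closed forests, and (b) the carbon-isotope record of leaf physiology.

`ringwue` implements that analysis end to end:

* **Growth model.** For observation *i* at site *s* in class *c*
  (cohort, or cohort × stand structure),

  log(growth)ᵢ ~ Normal(gᵢ, σ²ₚ),
  gᵢ = αₛ + β₁c·Precipᵢ + β₂c·MaxTempᵢ + β₃c·(MaxTemp×Precip)ᵢ
      + β₄c·lag1ᵢ + β₅c·lag2ᵢ + β₆c·DBHᵢ

  with covariates z-scored within class, site random intercepts
  αₛ ~ N(μ_α, σ²_α), class random slopes β_kc ~ N(μ_βk, σ²_βkc),
  hyper-means Uniform(−2, 2) and inverse-gamma(0.001, 0.001) variances.
  All full conditionals are conjugate and the model is fitted by a
  hand-written Gibbs sampler with Gelman–Rubin diagnostics, DIC and
  held-out R²/MSPE/bias.

* **Isotope physiology.** Latewood δ¹³C (‰ VPDB) is Suess-corrected,
  converted to discrimination Δ¹³C = (δₐ − δ_plant)/(1 + δ_plant/1000)
  = a + (b − a)·ci/ca with a = 4.4‰, b = 27‰, and to
  iWUE = (ca − ci)/1.6 = ca(b − Δ¹³C)/(1.6(b − a)). A hierarchical
  model with class baselines α_c and climate/size slopes estimates the
  modern-vs-past baseline iWUE increase attributable to CO2.

* **Projection.** Posterior-predictive ring width over temperature ×
  precipitation grids, percent change relative to the regional median
  June maximum (26 °C), modern-vs-past growth benefit, and climate
  scenario summaries.

* **Synthetic data.** A generator that reproduces the study design
  (9 sites on a 577–873 mm moisture gradient, 54 past + 49 modern trees,
  72 savanna / 31 forest, lag-autocorrelated lognormal growth, isotope
  series inverted through the discrimination identities) so the whole
  pipeline is testable without the archived field data.

## Worked example

Simulate the default study design, fit the structure–cohort growth model
(3 chains × 4000 Gibbs iterations), and inspect class sensitivities:

```python
from ringwue import synthetic_data as sd, io_ingest, climate_prep
from ringwue.growth_model import ModelSpec, SamplerSettings, sample_posterior

cfg = sd.SimConfig(seed=1)
monthly = sd.simulate_climate(cfg)
series, metas, truth = sd.simulate_growth(config=cfg, monthly=monthly)
annual = climate_prep.build_annual_climate(monthly)
obs = io_ingest.assemble_observations(series, metas, annual)
obs = io_ingest.assign_groups(obs, "cohort_structure")
obs, scaling = climate_prep.scale_covariates(obs)

fit = sample_posterior(obs, ModelSpec(), SamplerSettings(seed=1))
names = ["beta_precip[Past-Savanna]", "beta_precip[Modern-Savanna]",
         "beta_tmax[Past-Savanna]", "beta_interaction[Modern-Savanna]",
         "beta_lag1[Past-Savanna]", "sigma2_p"]
print(fit.summary().loc[names, ["mean", "q2.5", "q97.5"]].round(3))
```

```
                                   mean   q2.5  q97.5
beta_precip[Past-Savanna]         0.109  0.096  0.121
beta_precip[Modern-Savanna]       0.011 -0.001  0.024
beta_tmax[Past-Savanna]          -0.071 -0.084 -0.059
beta_interaction[Modern-Savanna]  0.064  0.051  0.076
beta_lag1[Past-Savanna]           0.559  0.520  0.595
sigma2_p                          0.087  0.084  0.090
```

Past-savanna growth is strongly precipitation-sensitive (0.109 per sd of
water-year precipitation) while the modern class is not (0.011); June
maximum temperature depresses growth; the modern savanna class shows a
positive temperature × precipitation interaction (high temperatures hurt
most when precipitation is low); and growth is strongly autocorrelated.
These posterior means recover the coefficients the dataset was generated
with (the generator's defaults), and σ²ₚ recovers the generating process
variance 0.09.

The same pipeline is available as a CLI:

```
ringwue --seed 1 --outdir runs/demo simulate
ringwue --seed 1 --outdir runs/demo prepare
ringwue --seed 1 --outdir runs/demo fit-growth
ringwue --seed 1 --outdir runs/demo fit-isotope
ringwue --seed 1 --outdir runs/demo predict
ringwue --seed 1 --outdir runs/demo report
```

## Layout

```
src/ringwue/
  io_ingest.py       Tucson .rwl / CSV readers and writers, cohort
                     assignment, DBH reconstruction, table assembly
  climate_prep.py    water-year aggregation, drought-year filter, class
                     scaling, train/test split, climate-matched years
  growth_model.py    hierarchical growth model, Gibbs sampler, diagnostics
  isotope_model.py   Suess correction, discrimination, iWUE, isotope fits
  prediction.py      posterior-predictive grids, contrasts, scenarios
  synthetic_data.py  study-design simulator (climate, rings, isotopes)
  cli.py             the six-command pipeline
docs/methods.md      model and generator documentation
```
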