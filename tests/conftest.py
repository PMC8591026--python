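import numpy as np
import pandas as pd
import pytest

from ringwue import climate_prep, io_ingest, synthetic_data


def small_config(seed: int = 11) -> synthetic_data.SimConfig:
    """A reduced tree design for fast unit tests (structure preserved:
    both cohorts at every site, savannas heavier than forests)."""
    return synthetic_data.SimConfig(seed=seed, savanna_trees=(6, 6),
                                    forest_trees=(4, 4))


@pytest.fixture(scope="session")
def small_dataset():
    """Simulated rings + metadata + climate, small enough for quick fits."""
    cfg = small_config()
    monthly = synthetic_data.simulate_climate(cfg)
    series, metas, truth = synthetic_data.simulate_growth(
        config=cfg, monthly=monthly)
    annual = climate_prep.build_annual_climate(monthly)
    return {"config": cfg, "monthly": monthly, "annual": annual,
            "series": series, "metas": metas, "truth": truth}


@pytest.fixture(scope="session")
def small_obs(small_dataset):
    """Assembled, grouped and scaled observation table."""
    obs = io_ingest.assemble_observations(small_dataset["series"],
                                          small_dataset["metas"],
                                          small_dataset["annual"])
    obs = io_ingest.assign_groups(obs, "cohort_structure")
    obs, scaling = climate_prep.scale_covariates(obs)
    return obs, scaling


@pytest.fixture(scope="session")
def small_fit(small_obs):
    """A quick Gibbs fit of the small dataset (2 chains x 800 iterations)."""
    from ringwue.growth_model import ModelSpec, SamplerSettings, sample_posterior
    obs, _ = small_obs
    settings = SamplerSettings(iterations=800, burn_in=400, thin=2,
                               chains=2, seed=11)
    return sample_posterior(obs, ModelSpec(), settings)


@pytest.fixture()
def annual_flat():
    """Constant annual climate covering 1880-2015 for one site."""
    years = np.arange(1880, 2016)
    return pd.DataFrame({"site_id": "S1", "year": years,
                         "wy_precip": 700.0, "june_tmax": 25.0,
                         "jja_pdsi": 0.0})
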