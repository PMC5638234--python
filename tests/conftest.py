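import numpy as np
import pandas as pd
import pytest

from stomatafit.dataset import COLUMNS, SpeciesDataset
from stomatafit.synthetic import (CampaignConfig, draw_true_species,
                                  simulate_campaign)


def make_dataset(species_id="test", n=60, seed=0, **overrides):
    """Small hand-rolled campaign with independent covariates (no coupled
    physics), for unit tests that need full control of the columns."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "gs": rng.uniform(0.02, 0.4, n),
        "A": rng.uniform(2.0, 18.0, n),
        "Cs": rng.normal(400.0, 5.0, n),
        "D": rng.uniform(0.3, 3.5, n),
        "Tleaf": rng.normal(25.0, 3.0, n),
        "psi_md": -rng.uniform(0.1, 3.0, n),
        "psi_pd": -rng.uniform(0.05, 2.0, n),
        "PAR": rng.uniform(300.0, 2000.0, n),
    })[COLUMNS]
    for col, vals in overrides.items():
        df[col] = vals
    return SpeciesDataset(species_id=species_id, data=df, p50=-3.0, p88=-4.5)


@pytest.fixture
def simple_dataset():
    return make_dataset()


@pytest.fixture(scope="session")
def coupled_species():
    """One conservative BBL.H species drawn from the panel priors."""
    rng = np.random.default_rng(42)
    return draw_true_species(rng, "CPL", conservative=True,
                             truth_model="BBL.H")


@pytest.fixture(scope="session")
def noiseless_campaign(coupled_species):
    sp = coupled_species
    cfg = CampaignConfig(n_obs=250, psi_min=-(abs(sp.psi_gs50_true) + 1.0),
                         gs_noise_cv=0.0, psi_noise_sd=0.0, seed=7)
    return simulate_campaign(sp, cfg)


@pytest.fixture(scope="session")
def noisy_campaign(coupled_species):
    sp = coupled_species
    cfg = CampaignConfig(n_obs=250, psi_min=-(abs(sp.psi_gs50_true) + 1.0),
                         seed=7)
    return simulate_campaign(sp, cfg)
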