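import numpy as np
import pandas as pd
import pytest

from salmonsize.reconstruct import reconstruct
from salmonsize.simulate import TruthConfig, simulate_covariates, simulate_population


@pytest.fixture(scope="session")
def tiny_world():
    """Fully expandable synthetic world: ~6000 fish total (2 rivers x 10
    brood years x ~300 fish), sampled densely so every cell has AL data."""
    truth = TruthConfig(
        rivers=("wood", "kvichak"),
        brood_years=(1990, 1999),
        mean_return=300.0,
        return_cv=0.3,
        sampling_frac_catch=0.25,
        sampling_frac_escapement=0.25,
        seed=7,
    )
    covars = simulate_covariates((1985, 2008), seed=7)
    world = simulate_population(truth, covars)
    recon = reconstruct(world["al_samples"], world["brood_table"], seed=7)
    return {"truth": truth, "covars": covars, "world": world, "recon": recon}


@pytest.fixture(scope="session")
def small_world():
    """Moderate synthetic world for statistical checks (3 rivers, 31 brood
    years, ~2e5 fish per river-year)."""
    truth = TruthConfig(
        rivers=("wood", "kvichak", "egegik"),
        brood_years=(1975, 2005),
        mean_return=2.0e5,
        sampling_frac_catch=4e-3,
        sampling_frac_escapement=4e-3,
        seed=11,
    )
    covars = simulate_covariates((1970, 2015), seed=11)
    world = simulate_population(truth, covars)
    recon = reconstruct(world["al_samples"], world["brood_table"], seed=11)
    return {"truth": truth, "covars": covars, "world": world, "recon": recon}


@pytest.fixture
def single_cell_al():
    """400 escapement AL samples for one (river, return year, age) cell."""
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "river": "wood",
        "return_year": 1995,
        "age_code": "1.3",
        "length_mm": rng.normal(550, 30, 400).round(1),
        "source": "escapement",
        "district": pd.NA,
        "mass_g": np.nan,
    })
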