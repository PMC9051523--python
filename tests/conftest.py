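import numpy as np
import pytest

from nfertpolicy import pipeline as pl
from nfertpolicy.synthetic_fields import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale study population (24 trial + 120 evaluation fields,
    10 weather years), generated once per session."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def run_config():
    return pl.RunConfig()


@pytest.fixture(scope="session")
def base_run(default_dataset, run_config):
    """Base-level leave-one-year-out run shared across tests."""
    return pl.run_base(default_dataset, run_config.prices, seed=0)


def hand_curve(n_grid, yields, leach2=None, region="central", field_id=0, year=0):
    """A hand-built response curve dict for arithmetic checks."""
    n_grid = np.asarray(n_grid, dtype=float)
    yields = np.asarray(yields, dtype=float)
    if leach2 is None:
        leach2 = np.linspace(10.0, 10.0 + len(n_grid) - 1, len(n_grid))
    return {
        "field_id": field_id,
        "year": year,
        "region": region,
        "n_grid": n_grid,
        "yield_at": yields,
        "leach2_at": np.asarray(leach2, dtype=float),
        "covariates_v5": {},
    }
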