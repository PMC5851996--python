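import numpy as np
import pytest

from mibird import MIBIRD_U_F, MIBIRD_U_R
from mibird.simulate import SimulationConfig, SitePlan, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A 24-record panel with two planted primer-region deletions."""
    plans = {0: SitePlan(delete_fwd=True), 1: SitePlan(delete_rev=True)}
    cfg = SimulationConfig(seed=11, n_species=24, site_plans=plans)
    records, truth = simulate_panel(cfg)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def primers():
    return MIBIRD_U_F, MIBIRD_U_R
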