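import numpy as np
import pytest
from hypothesis import settings

from landgas import (
    DecayParams,
    EmissionParams,
    MTMParams,
    SyntheticConfig,
    generate_panel,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def params() -> EmissionParams:
    """Study defaults: MSW_F 0.7, MCF 0.6, DOC 0.114, DOC_F 0.77, F 0.5."""
    return EmissionParams()


@pytest.fixture
def decay() -> DecayParams:
    return DecayParams(t_half=7.0)


@pytest.fixture
def unit_mtm() -> MTMParams:
    """Unit generation potential: profile sums to the bare 1.87 coefficient."""
    return MTMParams(c0=1.0)


@pytest.fixture
def small_panel():
    """8-state noisy panel, 1999-2015, calibrated national base-year total."""
    cfg = SyntheticConfig(n_states=8, seed=7)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


@pytest.fixture
def noise_free_panel():
    cfg = SyntheticConfig(n_states=10, seed=3, noise_sd=0.0, waste_elasticity=1.0)
    panel, truth = generate_panel(cfg)
    return cfg, panel, truth


def random_deposit_series(seed: int, n_years: int = 30, start: int = 1990):
    """Arbitrary non-negative deposition history for oracle comparisons."""
    rng = np.random.default_rng(seed)
    masses = rng.uniform(0.0, 50.0, size=n_years)
    masses[rng.random(n_years) < 0.1] = 0.0  # idle years happen
    return start, masses
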