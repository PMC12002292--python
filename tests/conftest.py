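"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from visuomotor.regressors import make_kernel
from visuomotor.synthetic_data import SimConfig, generate_population


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale dataset: enough neurons to exercise selection quickly."""
    return SimConfig(
        n_fish=2,
        n_sensory_per_stimulus=5,
        n_sm_per_behavior=5,
        n_mixed=2,
        n_background=50,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_population(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Deterministic responses: no noise, no amplitude jitter."""
    return SimConfig(
        n_fish=1,
        n_sensory_per_stimulus=3,
        n_sm_per_behavior=3,
        n_mixed=0,
        n_background=5,
        noise_sd=0.0,
        amp_spread_sd=0.0,
        trial_jitter_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_population(clean_config)


@pytest.fixture(scope="session")
def kernel2hz():
    return make_kernel(3.5, 2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
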