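"""Shared fixtures: one large published-profile simulation and its fitted
measurement model, reused across recovery and reporting tests."""

import numpy as np
import pytest

from careclass import published_profile_config, simulate, fit_measurement


@pytest.fixture(scope="session")
def profile_sim():
    """J=30 countries x 500 women drawn from the published class profile."""
    config = published_profile_config(J=30, n_per_group=500, seed=1)
    data, covs, truth = simulate(config)
    return config, data, covs, truth


@pytest.fixture(scope="session")
def profile_fit(profile_sim):
    """K=2, M=2 measurement fit of the published-profile simulation."""
    _, data, _, _ = profile_sim
    return fit_measurement(data, K=2, M=2, n_starts=20, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
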