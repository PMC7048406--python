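import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import grassinvert as gi

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def endmembers():
    wl = np.arange(400.0, 1000.0, 2.3)
    return gi.make_endmembers(wl)


@pytest.fixture(scope="session")
def noiseless_campaign():
    cfg = gi.CampaignConfig(agb_noise_cv=0.0, ndvi_noise_sd=0.0, spectrum_noise_sd=0.0, seed=1)
    return gi.simulate_campaign(cfg)


@pytest.fixture(scope="session")
def noisy_campaign():
    return gi.simulate_campaign(gi.CampaignConfig(seed=7))


def normal_equations_ols(x, y):
    """Independent OLS oracle: solve X'X beta = X'y directly."""
    X = np.column_stack([np.asarray(x, float), np.ones(len(x))])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    return float(beta[0]), float(beta[1])  # slope, intercept
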