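import numpy as np
import pytest

from ctds.detection import DetectionConfig


@pytest.fixture(scope="session")
def hn_distances():
    """1,000 radial distances from the half-normal point-transect density
    (sigma = 8 m, w = 40 m), drawn independently of the package internals:
    the density r*exp(-r^2/(2 sigma^2)) is a truncated Rayleigh, sampled by
    rejection."""
    rng = np.random.default_rng(42)
    r = rng.rayleigh(8.0, 3000)
    r = r[r <= 40.0][:1000]
    assert len(r) == 1000
    return r


@pytest.fixture(scope="session")
def hn_config():
    return DetectionConfig("half_normal", truncation_w=40.0)


@pytest.fixture(scope="session")
def small_survey():
    """A small simulated survey shared across tests (10 days, seed 1)."""
    from ctds.synthetic import SimulationConfig, simulate_survey

    cfg = SimulationConfig(seed=1, n_days=10)
    records, deployments, truth = simulate_survey(cfg)
    return cfg, records, deployments, truth
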