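import numpy as np
import pytest

from emergebayes import (
    EmergenceDataset,
    ModelParams,
    PriorSpec,
    SamplerConfig,
    fit_mcmc,
    simulate_tray,
)

#: true parameters used for simulation-based checks: a healthy maize tray
#: (95% yield, uniformity 1.6 /day, half-time 4.3 days)
TRUTH = ModelParams(0.95, 1.6, 4.3)


@pytest.fixture(scope="session")
def default_prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def toy_tray() -> EmergenceDataset:
    """Three seeds: one emerged in [0, 24 h), one in [24, 48 h), one censored."""
    return EmergenceDataset(edges=[0.0, 24.0, 48.0], counts=[1, 1], n_censored=1)


@pytest.fixture(scope="session")
def sim_tray() -> EmergenceDataset:
    """One simulated 110-seed tray observed every 2 h for 12 days."""
    return simulate_tray(TRUTH, seed=20260929, label="sim")


@pytest.fixture(scope="session")
def sim_fit(sim_tray, default_prior):
    """A moderate-length posterior fit of the simulated tray, shared by
    tests that only need plausible correlated posterior draws."""
    config = SamplerConfig(chains=2, n_iter=4000, n_burnin=2000, seed=42)
    return fit_mcmc(sim_tray, default_prior, config)
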