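import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import iasfit as F

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def feasible_params() -> F.CombinedParameters:
    """One rejection-sampled vector satisfying every constraint."""
    return F.sample_params(seed=12345)


@pytest.fixture(scope="session")
def feasible_cohort() -> list:
    """Thirty feasible vectors for prior-building tests."""
    rng = np.random.default_rng(99)
    return [F.sample_params(rng) for _ in range(30)]


@pytest.fixture(scope="session")
def noiseless_patient(feasible_params):
    """A noiseless synthetic record generated from feasible_params."""
    return F.generate_patient(feasible_params, noise_sd=0.0, seed=0)


@pytest.fixture()
def tiny_fit_config() -> F.FitConfig:
    """A minuscule optimizer budget for smoke tests of the fitting path."""
    return F.FitConfig(use_prior=False, de_maxiter=40, de_popsize=6,
                       n_restarts=1, seed=0)
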