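import numpy as np
import pytest

from pmgam import (
    calibrate_intercept,
    default_true_model,
    generate_covariates,
    linear_predictor,
    simulate_deaths,
)


@pytest.fixture(scope="session")
def cov1096():
    """One 1096-day covariate realization (with 7-day PM2.5 history)."""
    return generate_covariates(1096, seed=0)


@pytest.fixture(scope="session")
def truth(cov1096):
    """Default generative truth with the intercept anchored to 32 deaths/day."""
    return calibrate_intercept(default_true_model(), cov1096)


@pytest.fixture(scope="session")
def mean_series(truth, cov1096):
    return np.exp(linear_predictor(truth, cov1096))


@pytest.fixture(scope="session")
def sim_halfnoise(mean_series, truth):
    """One simulated series at gamma = 0.5 (the real-data-like noise level)."""
    return simulate_deaths(mean_series, 0.5, truth.sigma_hat, seed=1)


@pytest.fixture(scope="session")
def cov400():
    """Short covariate draw for fast fitting tests."""
    return generate_covariates(400, seed=7)
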