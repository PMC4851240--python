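import numpy as np
import pytest

from blindsr import EndpointParams, Stage1Data, TrialDesign, UNBOUNDED
from blindsr.model import conditional_error_blinded
from blindsr.params import ConditionalLaw


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def informative_params():
    """Secondary endpoint with a clear treatment effect; no correlation."""
    return EndpointParams(mu0=0.0, mu1=0.0, nu0=0.0, nu1=2.0, sigma=1.0, rho=0.0)


@pytest.fixture
def uninformative_params():
    """Identical arms: the blinded data carry no allocation information."""
    return EndpointParams(mu0=0.0, mu1=0.0, nu0=1.0, nu1=1.0, sigma=1.0, rho=0.3)


def grid_search_max_ce(mean, variance, n1, n2min, n2max, alpha, n_points=10_000):
    """Brute-force maximum of the blinded conditional error over an n2 grid.

    Independent oracle for the closed-form reassessment rule: logarithmic
    grid plus both endpoints (and the unbounded sentinel when applicable).
    """
    law = ConditionalLaw(mean=mean, variance=variance)
    hi = n2max if np.isfinite(n2max) else 1e6 * n1
    grid = np.geomspace(max(n2min, 1e-6), hi, n_points)
    grid = np.concatenate([[n2min], grid, [n2max] if np.isfinite(n2max) else [np.inf]])
    return float(np.max(conditional_error_blinded(law, n1, grid, alpha)))


@pytest.fixture
def grid_oracle():
    return grid_search_max_ce
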