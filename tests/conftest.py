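import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from epiident import EpidemicParams, ModelSpec, integrate

GAMMA7 = 1.0 / 7.0

ALL_SPECS = [ModelSpec(m) for m in ("sir", "pairwise_binomial", "pairwise_poisson", "ebcm")]


def supercritical_params(model_id: str, r0_equiv: float = 2.5, gamma: float = GAMMA7,
                         n: float = 6.0, N: float = 10_000.0) -> EpidemicParams:
    """Parameters with tau*l(n)/gamma equal to the requested ratio."""
    slope = ModelSpec(model_id).eigen_slope(n)
    return EpidemicParams(tau=r0_equiv * gamma / slope, gamma=gamma, n=n, N=N)


@pytest.fixture(scope="session")
def baseline_pairwise_params() -> EpidemicParams:
    """The indistinguishability-experiment baseline: tau = gamma = 1/7, n = 6."""
    return EpidemicParams(tau=GAMMA7, gamma=GAMMA7, n=6.0, N=10_000.0)


@pytest.fixture(scope="session")
def baseline_pairwise_trajectory(baseline_pairwise_params):
    return integrate(ModelSpec("pairwise_binomial"), baseline_pairwise_params)


@pytest.fixture(scope="session")
def sir_growth_trajectory():
    """Supercritical sir run with lam = 0.3/day, reused across estimator tests."""
    return integrate(ModelSpec("sir"), EpidemicParams(tau=0.1, gamma=0.2, n=5.0, N=10_000.0))
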