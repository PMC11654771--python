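import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import integrate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mga_mse_cohort():
    from webergrasp import generate_mga_mse_cohort

    return generate_mga_mse_cohort(seed=777)


def jzs_bf10_oracle(t: float, n: int, rscale: float) -> float:
    """Independent JZS Bayes factor via the Rouder g-mixture integral.

    The Cauchy prior on effect size is a scale mixture of normals with an
    inverse-chi-square mixing density on g; integrating g out gives the
    marginal likelihood under H1 without ever touching the noncentral-t
    density used by the implementation.
    """
    nu = n - 1

    def integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t**2 / ((1 + n * g) * nu)) ** (-(nu + 1) / 2.0)
            * (2 * math.pi) ** -0.5
            * g**-1.5
            * rscale
            * math.exp(-(rscale**2) / (2 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, epsabs=1e-14, epsrel=1e-12, limit=400)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2.0)
    return num / den
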