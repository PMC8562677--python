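import numpy as np
import pytest

from utilitr import GenerativeConfig, fit_q, simulate


@pytest.fixture(scope="session")
def fixed_config():
    """Fixed-utility, constant-propensity design (omega=0.25, rho=0.6)."""
    return GenerativeConfig(n=500, utility=0.25, behavior=0.6, seed=42)


@pytest.fixture(scope="session")
def fixed_cohort(fixed_config):
    return simulate(fixed_config)


@pytest.fixture(scope="session")
def fixed_qmodels(fixed_cohort):
    return fit_q(fixed_cohort, "y"), fit_q(fixed_cohort, "z")


@pytest.fixture(scope="session")
def varying_config():
    """Patient-specific utility design: w(x)=expit(1-0.5*x1), beta=(0.5,1,0,...)."""
    return GenerativeConfig(n=500, utility=(1.0, -0.5, 0, 0, 0, 0),
                            behavior=(0.5, 1.0, 0, 0, 0, 0), seed=11)


@pytest.fixture(scope="session")
def varying_cohort(varying_config):
    return simulate(varying_config)


@pytest.fixture(scope="session")
def varying_qmodels(varying_cohort):
    return fit_q(varying_cohort, "y"), fit_q(varying_cohort, "z")


@pytest.fixture(scope="session")
def bivariate_config():
    """Bivariate-covariate design used for bootstrap inference checks."""
    return GenerativeConfig(n=500, p=2, utility=(1.0, 0.0, 0.0),
                            behavior=(2.5, 1.0, 0.0), seed=5)


@pytest.fixture(scope="session")
def bivariate_cohort(bivariate_config):
    return simulate(bivariate_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
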