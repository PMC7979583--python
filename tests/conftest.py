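import numpy as np
import pytest

from vaptmdd import (
    Subject,
    apply_covariates,
    default_omega_sigma,
    default_parameters,
)


@pytest.fixture(scope="session")
def theta():
    return default_parameters()


@pytest.fixture(scope="session")
def osig():
    return default_omega_sigma()


@pytest.fixture(scope="session")
def typical_subject():
    return Subject(id=1, sex="male", egfr=44.0)


@pytest.fixture(scope="session")
def typical_ip(theta, typical_subject):
    """Individual parameters of the typical male subject with eGFR 44."""
    return apply_covariates(theta, typical_subject)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
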