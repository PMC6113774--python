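import numpy as np
import pytest

from dermadyn import datasets


@pytest.fixture(scope="session")
def published():
    return datasets.published_fit()


@pytest.fixture(scope="session")
def pf_data():
    return datasets.pf_observations()


@pytest.fixture(scope="session")
def ecm_data():
    return datasets.ecm_observations()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# Mean square deviations of the published parameterisation from the two
# measured tables, computed once with a plain solve_ivp reimplementation
# (integrate, evaluate at the table times, average the squared residuals)
# and frozen as regression values.
PUBLISHED_MSE_PF = 16.091445
PUBLISHED_MSE_ECM = 14.377495


@pytest.fixture(scope="session")
def published_mse():
    return PUBLISHED_MSE_PF, PUBLISHED_MSE_ECM
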