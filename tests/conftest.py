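import pytest

from losartan_pkpd import reference_parameters, reference_regimen, simulate


@pytest.fixture(scope="session")
def wt_params():
    return reference_parameters("*1/*1")


@pytest.fixture(scope="session")
def regimen():
    return reference_regimen()


@pytest.fixture(scope="session")
def wt_sim(wt_params, regimen):
    """Dense wild-type reference simulation, shared across tests."""
    return simulate(wt_params, regimen)
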