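import pytest

from trialpool.pipeline_des import base_phase_params
from trialpool.synthetic_data import worked_fixture


@pytest.fixture(scope="session")
def base_params():
    return base_phase_params()


@pytest.fixture()
def fixture_portfolio():
    return worked_fixture()[0]


@pytest.fixture()
def fixture_epi():
    return worked_fixture()[1]


@pytest.fixture()
def fixture_disease(fixture_epi):
    return fixture_epi["malaria"]
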