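import pytest
from hypothesis import settings

from bpascreen import builtin_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def hr_panel():
    return builtin_fixture("hr_named")


@pytest.fixture(scope="session")
def control_panel():
    return builtin_fixture("controls")


@pytest.fixture(scope="session")
def hr67(hr_panel):
    return hr_panel["HR67"]
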