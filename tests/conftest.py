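import pytest

from biphasic_cea import SOCIETAL, default_config


@pytest.fixture(scope="session")
def hcp_config():
    """Base case: healthcare-sector perspective, 10-fold risk reduction."""
    return default_config()


@pytest.fixture(scope="session")
def societal_config():
    """Base case with indirect (job-opportunity) costs included."""
    return default_config(perspective=SOCIETAL)
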