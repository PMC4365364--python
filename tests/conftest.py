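import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from gva.datasets import (  # noqa: E402
    protective_contrast_tables,
    rheumatoid_arthritis_panel,
    risk_contrast_tables,
)


@pytest.fixture(scope="session")
def ra_panel():
    return rheumatoid_arthritis_panel()


@pytest.fixture(scope="session")
def risk_tables():
    return risk_contrast_tables()


@pytest.fixture(scope="session")
def protective_tables():
    return protective_contrast_tables()
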