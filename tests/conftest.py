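import pytest
from hypothesis import HealthCheck, settings

import leafcoex as lx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return lx.load_table1()


@pytest.fixture(scope="session")
def catalogue():
    return lx.load_aquaporin_catalogue()


@pytest.fixture()
def collapsed(table1):
    table, _ = lx.collapse_duplicates(table1.copy())
    return table
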