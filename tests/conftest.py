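import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    """Default synthetic gadoid reference panel (fixed seed)."""
    from fishauth.synthetic import simulate_reference_panel

    return simulate_reference_panel(seed=0)


@pytest.fixture(scope="session")
def rules():
    from fishauth.concordance import default_rules

    return default_rules()


@pytest.fixture(scope="session")
def fixture_table2():
    from fishauth.concordance import load_table2_fixture

    return load_table2_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
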