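import pytest

from adscreen.parameters import paper_default
from adscreen.screening import ScreeningPolicy
from adscreen.synthetic import SyntheticConfig, generate_paramset


@pytest.fixture(scope="session")
def default_params():
    return paper_default()


@pytest.fixture()
def params(default_params):
    """A mutable copy of the shipped defaults."""
    return default_params.copy()


@pytest.fixture(scope="session")
def anchored_params():
    """One seeded paper-anchored synthetic parameter set."""
    return generate_paramset(SyntheticConfig(seed=42, realism="paper_anchored"))


@pytest.fixture(scope="session")
def once_policy():
    return ScreeningPolicy(start_age=60, interval="once")
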