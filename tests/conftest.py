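import pytest

from spbudget.model import load_scenario_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """The three packaged intervention scenarios, keyed by id."""
    return {s.id: s for s in load_scenario_fixtures()}


@pytest.fixture
def socialisation(fixtures):
    return fixtures["socialisation"]


@pytest.fixture
def large_groups(fixtures):
    return fixtures["large_groups"]


@pytest.fixture
def pheromones(fixtures):
    return fixtures["pheromones"]
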