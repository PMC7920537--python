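import pytest

from otosplice.simulate import (
    SimulationConfig,
    make_fixture,
    simulate_fixture_counts,
)


@pytest.fixture(scope="session")
def tmc1():
    return make_fixture("tmc1_like")


@pytest.fixture(scope="session")
def lhfpl5():
    return make_fixture("lhfpl5_like")


@pytest.fixture(scope="session")
def tmie():
    return make_fixture("tmie_like")


@pytest.fixture(scope="session")
def fixtures(tmc1, lhfpl5, tmie):
    return {"tmc1_like": tmc1, "lhfpl5_like": lhfpl5, "tmie_like": tmie}


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def sim_tables(fixtures, sim_config):
    """Default-mixture junction counts per fixture (seeded, deterministic)."""
    return {
        name: simulate_fixture_counts(fx, sim_config)
        for name, fx in fixtures.items()
    }
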