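import pytest

from rebakit.anthropometry import Sex, build_mannequin
from rebakit.fixtures import DEFAULT_POPULATION, make_fixture_stations


@pytest.fixture(scope="session")
def population():
    return DEFAULT_POPULATION


@pytest.fixture(scope="session")
def stations(population):
    """The two synthetic fixture stations (assembly bench, hanging tool)."""
    return make_fixture_stations(population, seed=0)


@pytest.fixture(scope="session")
def p5_female(population):
    return build_mannequin(population, Sex.FEMALE, 5.0)


@pytest.fixture(scope="session")
def p95_male(population):
    return build_mannequin(population, Sex.MALE, 95.0)


@pytest.fixture(scope="session")
def p50_combined(population):
    return build_mannequin(population, Sex.COMBINED, 50.0)
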