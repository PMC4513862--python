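"""Shared fixtures: toy systems, parameters, and enumeration oracles."""

import pytest
from hypothesis import settings

from hpk.energy import EnergyParams
from hpk.oracle import enumerate_states
from hpk.sequences import generate_toy_system

settings.register_profile("suite", deadline=None, max_examples=50,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


@pytest.fixture(scope="session")
def toy_plain():
    """8-nt complementary pair with no intra-strand structure."""
    return generate_toy_system(8, with_hairpin=False, seed=7)


@pytest.fixture(scope="session")
def toy_hairpin():
    """8-nt complementary pair whose probe carries a 2-bp stem."""
    return generate_toy_system(8, with_hairpin=True, seed=3)


@pytest.fixture(scope="session")
def toy_hairpin2():
    """A second hairpin toy with a different sequence."""
    return generate_toy_system(8, with_hairpin=True, seed=12)


@pytest.fixture(scope="session")
def space_plain(toy_plain, params):
    return enumerate_states(toy_plain, params)


@pytest.fixture(scope="session")
def space_hairpin(toy_hairpin, params):
    return enumerate_states(toy_hairpin, params)


@pytest.fixture(scope="session")
def space_hairpin2(toy_hairpin2, params):
    return enumerate_states(toy_hairpin2, params)
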