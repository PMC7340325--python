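import numpy as np
import pytest

from morphosim.fixtures import cells_fixture, lattice_fixture


@pytest.fixture(scope="session")
def small_lattice():
    """~200-site random close packing, shared across tests."""
    return lattice_fixture("small", seed=7)


@pytest.fixture(scope="session")
def tiny_lattice():
    return lattice_fixture("tiny", seed=7)


@pytest.fixture()
def ramp_cells(small_lattice):
    return cells_fixture(small_lattice, "ramp", seed=7)


@pytest.fixture()
def random_cells(small_lattice):
    return cells_fixture(small_lattice, "random", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
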