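import numpy as np
import pytest

from walkbym import build_grid_lattice, default_scenario


@pytest.fixture(scope="session")
def path4():
    """4-node path graph (smallest fixture with distinct neighbour counts)."""
    g = build_grid_lattice(1, 4, "rook")
    assert list(g.k) == [1, 2, 2, 1]
    return g


@pytest.fixture(scope="session")
def lattice33_rook():
    return build_grid_lattice(3, 3, "rook")


@pytest.fixture(scope="session")
def small_scenario():
    """36 contiguous areas, modest populations: fast full-pipeline fixture."""
    lattice = build_grid_lattice(6, 6, "queen")
    return default_scenario(seed=11).with_(graph=lattice, pop_median=80.0,
                                           pop_iqr=(50.0, 130.0))


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
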