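import numpy as np
import pytest

from hnmmc.model import BeadStructure
from hnmmc.synthetic import (ToySpec, go_bead_types, make_go_potential,
                             make_toy_complex)


@pytest.fixture(scope="session")
def toy():
    """Default two-anchor toy complex: (structure, hierarchy, probes)."""
    return make_toy_complex(ToySpec())


@pytest.fixture(scope="session")
def toy_potential(toy):
    structure, _, _ = toy
    return make_go_potential(structure, ToySpec())


@pytest.fixture(scope="session")
def toy_bead_types(toy):
    return go_bead_types(toy[0])


def small_structure(n_res=5, seed=0, chain="A"):
    """A compact single-chain structure with valid virtual bonds."""
    rng = np.random.default_rng(seed)
    residues = []
    pos = np.zeros(3)
    for i in range(n_res):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        if i:
            pos = pos + 0.38 * direction
        ca = pos.copy()
        o = ca + np.array([0.1, 0.1, 0.18])
        sc = ca + np.array([0.0, 0.0, 0.2])
        residues.append((i + 1, "A", ca, o, sc))
    return BeadStructure.from_chains([(chain, residues)])


@pytest.fixture
def pentamer():
    return small_structure()
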