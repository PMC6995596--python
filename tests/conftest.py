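import numpy as np
import pytest

from tetra import synthdata
from tetra.structio import AtomicModel


@pytest.fixture(scope="session")
def toy2():
    """Two-chain helix toy model with CA/CB anchors."""
    return synthdata.toy_model(n_chains=2, residues_per_chain=20, seed=7)


@pytest.fixture(scope="session")
def bipartite():
    return synthdata.bipartite_model(core_radius=2.0, arm_length=6.0, seed=3)


@pytest.fixture()
def square_model():
    """Four CA atoms on a square, handy for exact RMSD checks."""
    coords = np.array(
        [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [4.0, 4.0, 0.0], [0.0, 4.0, 0.0]]
    )
    return AtomicModel(
        np.array(["A"] * 4),
        np.arange(1, 5),
        np.array(["ALA"] * 4),
        np.array(["CA"] * 4),
        coords,
    )
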