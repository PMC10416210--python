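import numpy as np
import pytest

from ccorigami.builder import build_origami, default_topology, dimer_structure
from ccorigami.structures import Atom, Residue, Structure


@pytest.fixture(scope="session")
def triangle_model():
    """Paper-condition triangle: edges 47/34/47 Å, GSG linkers, alternating
    inner/outer packing with plane crossing (knotted fold)."""
    return build_origami(default_topology())


@pytest.fixture(scope="session")
def planar_model():
    """In-plane control with nested (non-crossing) passes."""
    return build_origami(default_topology(plane_crossing=False))


@pytest.fixture(scope="session")
def ideal_dimer():
    """Ideal parallel dimer with side-chain stubs, 28 residues per chain."""
    return dimer_structure(n_res=28)


def structure_from_coords(coords, names=None):
    residues = [
        Residue(i + 1, (names[i] if names else "ALA"),
                [Atom("CA", "C", c)])
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]
    return Structure(chains={"A": residues})
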