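import numpy as np
import pytest

from pharmsig import Pharmacophore
from pharmsig.synthetic import make_planted_dataset


@pytest.fixture
def chiral_quad():
    """Four distinct labels at generic, non-planar positions (class ABCD)."""
    return Pharmacophore(
        [("a", 0, 0, 0), ("b", 2, 0, 0), ("c", 0, 2, 0), ("d", 0, 0, 2)]
    )


@pytest.fixture
def regular_tetrahedron():
    """Identically labelled regular tetrahedron, edge 3 Å (class AAAA)."""
    edge = 3.0
    verts = np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * (edge / np.sqrt(8.0))
    return Pharmacophore([("A", *map(float, v)) for v in verts])


@pytest.fixture(scope="session")
def planted():
    """Small planted-model dataset shared across modeling tests."""
    return make_planted_dataset(
        n_active=10, n_inactive=20, k=5, n_decoys=3, n_conformers=2, seed=1
    )
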