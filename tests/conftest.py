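import numpy as np
import pytest

from apoflow.fixtures import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_pair():
    """One deterministic toy apo/holo pair (ethanol ligand)."""
    return make_toy_complex(ToyComplexSpec(seed=4))


@pytest.fixture(scope="session")
def toy_pair_symmetric():
    """A toy pair with a symmetric ring ligand (benzene)."""
    return make_toy_complex(ToyComplexSpec(seed=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_ligand_graph(rng, max_atoms=12):
    """Random connected-ish bond graph for property tests."""
    from apoflow.chem import LigandGraph, _fragments_from_bonds

    n = int(rng.integers(2, max_atoms + 1))
    bonds = set()
    # random spanning structure over a random number of fragments
    order = rng.permutation(n)
    n_frag = int(rng.integers(1, min(3, n) + 1))
    cuts = sorted(rng.choice(np.arange(1, n), size=n_frag - 1, replace=False)) if n_frag > 1 else []
    groups = np.split(order, cuts)
    for grp in groups:
        for a, b in zip(grp, grp[1:]):
            bonds.add((min(a, b), max(a, b)))
        # a few extra intra-fragment edges
        if len(grp) > 2:
            for _ in range(int(rng.integers(0, 3))):
                a, b = rng.choice(grp, size=2, replace=False)
                if a != b:
                    bonds.add((min(a, b), max(a, b)))
    bonds = tuple(sorted(int(i) for i in b) for b in sorted(bonds))
    bonds = tuple((i, j) for i, j in bonds)
    return LigandGraph(
        n_atoms=n,
        elements=tuple("C" for _ in range(n)),
        bonds=bonds,
        fragment_id=_fragments_from_bonds(n, bonds),
    )
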