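import numpy as np
import pytest

from ampaflex import structure_io as sio
from ampaflex import synthetic_data as sd


@pytest.fixture(scope="session")
def scaffold():
    """Reference tetramer scaffold with default geometry."""
    return sd.build_scaffold()


@pytest.fixture(scope="session")
def selections():
    """Named selections matching the scaffold residue layout."""
    return sd.default_selections()


@pytest.fixture()
def toy_model():
    """4 chains x 10 residues of CA atoms on a simple lattice."""
    chain_ids, resnums, resnames, atoms, coords = [], [], [], [], []
    for ci, chain in enumerate("ABCD"):
        for r in range(1, 11):
            chain_ids.append(chain)
            resnums.append(r)
            resnames.append("GLY")
            atoms.append("CA")
            coords.append([ci * 10.0, r * 1.5, (ci - r) * 0.3])
    return sio.StructureModel(
        model_id="toy",
        chain_ids=np.array(chain_ids, dtype=object),
        residue_numbers=np.array(resnums, dtype=int),
        residue_names=np.array(resnames, dtype=object),
        atom_names=np.array(atoms, dtype=object),
        coords=np.array(coords, dtype=float),
    )


def random_rigid_transform(rng):
    """Random proper rotation + translation (helper for invariance tests)."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.uniform(-20, 20, size=3)
    return Q, t
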