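import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rdcfit import (
    FixtureSpec,
    default_tensor,
    extract_nh_vectors,
    make_structure,
    simulate_rdcs,
)
from rdcfit.structure import Atom


@pytest.fixture(scope="session")
def two_helix():
    """Two-helix fixture: structure, SSE definition, vectors, true tensor."""
    spec = FixtureSpec(kind="two_helix", n_residues=15, noise=0.0)
    structure, sses = make_structure(spec)
    vectors = extract_nh_vectors(structure, "A")
    return {
        "spec": spec,
        "structure": structure,
        "sses": sses,
        "vectors": vectors,
        "tensor": spec.tensor,
    }


@pytest.fixture(scope="session")
def noiseless_dataset(two_helix):
    return simulate_rdcs(two_helix["structure"], two_helix["tensor"], noise=0.0)


def rotate_element(structure, element, angle_deg, axis, chain="A"):
    """Rigidly rotate one SSE about its Cα centroid (test-side ground truth)."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis)
    centroid = np.mean(
        [structure.coords(chain, r, "CA") for r in element.residues()], axis=0
    )
    atoms = []
    for a in structure.atoms:
        if a.chain == chain and element.start <= a.resnum <= element.end:
            xyz = rot.as_matrix() @ (a.pos - centroid) + centroid
            atoms.append(Atom(a.chain, a.resnum, a.resname, a.name, *map(float, xyz)))
        else:
            atoms.append(a)
    return structure.with_atoms(atoms)


@pytest.fixture(scope="session")
def random_tensor_factory():
    def make(seed=0, Da=-12.0, R=0.25):
        rng = np.random.default_rng(seed)
        euler = rng.uniform([0, 10, 0], [360, 80, 360])
        return default_tensor(Da=Da, R=R, euler_zyz=tuple(euler))

    return make
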