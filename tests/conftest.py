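import warnings

import numpy as np
import pytest

from rpcdock import fixtures
from rpcdock.structure_io import assign_charges

warnings.filterwarnings("ignore", message="ligand chain")


@pytest.fixture(scope="session")
def toy():
    """Bound toy complex, seed 1: (protein, rna, native_pose, manifest)."""
    return fixtures.make_toy_complex(1)


@pytest.fixture(scope="session")
def toy_charged(toy):
    protein, rna, pose, manifest = toy
    protein_q, _ = assign_charges(protein)
    rna_q, _ = assign_charges(rna)
    return protein_q, rna_q, pose, manifest


@pytest.fixture(scope="session")
def training_library():
    from rpcdock.rprank import train_potential
    return train_potential(fixtures.make_training_set(0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
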