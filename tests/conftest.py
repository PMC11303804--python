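import numpy as np
import pytest

from euclidff.graph import AtomicSystem
from euclidff.network import ModelConfig, init_params
from euclidff.synthdata import HarmonicMolecule


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det +1)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model():
    """A small random-weight model plus a 6-atom molecule to probe it with."""
    cfg = ModelConfig(feature_dim=16, heads=4, blocks=2, degrees=(0, 1, 2, 3),
                      r_cut=4.0, n_rbf=8, mean_neighbors=3.0)
    params = init_params(cfg, seed=0)
    rng = np.random.default_rng(5)
    system = AtomicSystem([1, 6, 8, 1, 6, 1], rng.normal(size=(6, 3)) * 1.5)
    return cfg, params, system


@pytest.fixture
def triangle_molecule():
    """Equilateral harmonic triatomic at its minimum (C3, bonds k=5 eV/A^2)."""
    r0 = 1.5
    pot = HarmonicMolecule(bonds=((0, 1), (1, 2), (0, 2)), k=5.0, r0=r0)
    pos = np.array([
        [0.0, 0.0, 0.0],
        [r0, 0.0, 0.0],
        [0.5 * r0, 0.5 * np.sqrt(3) * r0, 0.0],
    ])
    return pot, AtomicSystem([6, 6, 6], pos)
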