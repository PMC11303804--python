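"""The Euclidean transformer force field.

An invariant feature vector f_i (dim F) and an equivariant spherical tensor
x_i (the "Euclidean variables", degrees l_min..l_max) live on every atom.
T transformer blocks alternate a Euclidean self-attention update (messages
along edges, attention coefficients built from invariant contractions only)
with a per-atom interaction block that mixes the two representations.  A
two-layer readout maps final features to per-atom energies whose sum is the
potential energy; forces are exact negative gradients obtained by reverse-
mode differentiation through the whole computation.

The geometry enters only through interatomic distances and spherical
harmonics of edge directions, so the energy is invariant and the force field
equivariant under rotations, translations, permutations and inversion by
construction — the test suite asserts this blockwise and end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Dict, Tuple

import numpy as np

from . import engine as eg
from .engine import Tensor
from .graph import AtomicSystem, NeighborList, build_neighbors
from .so3 import contraction_constant, num_components

__all__ = [
    "ModelConfig", "FeatureState", "EuclideanState", "init_params",
    "count_params", "embed", "init_ev", "cutoff", "rbf", "filter_w",
    "attention_coeffs", "attention_block", "interaction_block",
    "forward_energy", "forces", "energy_and_forces", "NetworkPotential",
]

_SUPPORTED_DEGREES = (0, 1, 2, 3)


@dataclass
class ModelConfig:
    """Hyperparameters of the Euclidean transformer.

    feature_dim F must be divisible by both the number of invariant heads h
    and the number of degrees (the EV attention branch uses one slice per
    degree).  RBF centers are spaced uniformly in [exp(-r_cut), 1] with
    gamma = (2/K * (1 - exp(-r_cut)))**-2.
    """

    feature_dim: int = 32          # F
    heads: int = 4                 # h
    blocks: int = 2                # T
    degrees: tuple = (1, 2)        # l_min .. l_max, ordered
    r_cut: float = 5.0
    n_rbf: int = 32                # K
    ev_init: str = "neighborhood"  # or "zeros"
    mean_neighbors: float = 1.0    # <N>, fixed from the training set
    max_atomic_number: int = 118

    def __post_init__(self):
        self.degrees = tuple(int(l) for l in self.degrees)
        if not self.degrees or any(l not in _SUPPORTED_DEGREES for l in self.degrees):
            raise ValueError(f"degrees must be a subset of {_SUPPORTED_DEGREES}")
        if list(self.degrees) != sorted(set(self.degrees)):
            raise ValueError("degrees must be strictly increasing")
        if self.feature_dim % self.heads:
            raise ValueError("feature_dim must be divisible by heads")
        if self.feature_dim % len(self.degrees):
            raise ValueError("feature_dim must be divisible by the number of degrees")
        if self.n_rbf < 1:
            raise ValueError("need at least one radial basis function")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.ev_init not in ("neighborhood", "zeros"):
            raise ValueError("ev_init must be 'neighborhood' or 'zeros'")

    @property
    def n_degrees(self) -> int:
        return len(self.degrees)

    @property
    def ev_dim(self) -> int:
        return num_components(self.degrees)

    @property
    def rbf_centers(self) -> np.ndarray:
        return np.linspace(np.exp(-self.r_cut), 1.0, self.n_rbf)

    @property
    def rbf_gamma(self) -> float:
        return (2.0 / self.n_rbf * (1.0 - np.exp(-self.r_cut))) ** -2

    def to_dict(self) -> dict:
        return {
            "feature_dim": self.feature_dim, "heads": self.heads,
            "blocks": self.blocks, "degrees": list(self.degrees),
            "r_cut": self.r_cut, "n_rbf": self.n_rbf, "ev_init": self.ev_init,
            "mean_neighbors": self.mean_neighbors,
            "max_atomic_number": self.max_atomic_number,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["degrees"] = tuple(d["degrees"])
        return cls(**d)


@dataclass
class FeatureState:
    """Per-atom invariant features; rotation invariant by construction."""

    values: np.ndarray  # n x F


@dataclass
class EuclideanState:
    """Per-atom packed spherical tensors (degree-major, m = -l..l)."""

    values: np.ndarray  # n x ev_dim
    degrees: tuple


# -- parameters --------------------------------------------------------------

def init_params(cfg: ModelConfig, seed: int = 0) -> Dict[str, Tensor]:
    """Random trainable parameters (LeCun-normal weights, zero biases)."""
    rng = np.random.default_rng(seed)
    F, K, nd = cfg.feature_dim, cfg.n_rbf, cfg.n_degrees
    Fh = F // 4
    p: Dict[str, np.ndarray] = {"embedding": rng.normal(size=(cfg.max_atomic_number, F))}
    for t in range(cfg.blocks):
        b = f"block{t}/"
        for name in ("Qf", "Kf", "Vf", "Qe", "Ke"):
            p[b + name] = rng.normal(size=(F, F)) / sqrt(F)
        p[b + "Wu1"] = rng.normal(size=(nd, Fh)) / sqrt(nd)
        p[b + "bu1"] = np.zeros(Fh)
        p[b + "Wu2"] = rng.normal(size=(Fh, F)) / sqrt(Fh)
        p[b + "bu2"] = np.zeros(F)
        p[b + "Wg1"] = rng.normal(size=(K, F)) / sqrt(K)
        p[b + "bg1"] = np.zeros(F)
        p[b + "Wg2"] = rng.normal(size=(F, F)) / sqrt(F)
        p[b + "bg2"] = np.zeros(F)
        p[b + "Wi"] = rng.normal(size=(F + nd, F + nd)) / sqrt(F + nd)
        p[b + "bi"] = np.zeros(F + nd)
    p["readout/W1"] = rng.normal(size=(F, F // 2)) / sqrt(F)
    p["readout/b1"] = np.zeros(F // 2)
    p["readout/W2"] = rng.normal(size=(F // 2, 1)) / sqrt(F // 2)
    p["readout/b2"] = np.zeros(1)
    p["shift"] = np.zeros(cfg.max_atomic_number)
    p["scale"] = np.ones(cfg.max_atomic_number)
    return {k: Tensor(v) for k, v in p.items()}


def count_params(params: Dict[str, Tensor]) -> int:
    """Exact number of scalar trainables."""
    return int(sum(p.data.size for p in params.values()))


def set_energy_statistics(params, mean_per_atom: float, std_per_atom: float = 1.0):
    """Initialize the per-element shift/scale from training-set statistics."""
    params["shift"] = Tensor(np.full_like(params["shift"].data, mean_per_atom))
    params["scale"] = Tensor(np.full_like(params["scale"].data, max(std_per_atom, 1e-12)))


# -- differentiable building blocks ------------------------------------------

# real spherical harmonics as Cartesian polynomials (orthonormal, matching
# so3.real_sph_harm component by component)
_C0 = 0.28209479177387814
_C1 = 0.4886025119029199
_C2A, _C2B, _C2C = 1.0925484305920792, 0.31539156525252005, 0.5462742152960396
_C3 = {
    -3: 0.5900435899266435, -2: 2.890611442640554, -1: 0.4570457994644658,
    0: 0.3731763325901154, 1: 0.4570457994644658, 2: 1.445305721320277,
    3: 0.5900435899266435,
}


def _sph_columns(unit: Tensor, degrees) -> Tensor:
    """Spherical harmonics of edge directions, traced for autodiff. E x D."""
    x = unit[:, 0:1]
    y = unit[:, 1:2]
    z = unit[:, 2:3]
    cols = []
    for l in degrees:
        if l == 0:
            cols.append(Tensor(np.full((unit.shape[0], 1), _C0)))
        elif l == 1:
            cols += [_C1 * y, _C1 * z, _C1 * x]
        elif l == 2:
            zz = z * z
            cols += [
                _C2A * x * y, _C2A * y * z, _C2B * (3.0 * zz - 1.0),
                _C2A * x * z, _C2C * (x * x - y * y),
            ]
        elif l == 3:
            xx, yy, zz = x * x, y * y, z * z
            cols += [
                _C3[-3] * y * (3.0 * xx - yy),
                _C3[-2] * x * y * z,
                _C3[-1] * y * (5.0 * zz - 1.0),
                _C3[0] * z * (5.0 * zz - 3.0),
                _C3[1] * x * (5.0 * zz - 1.0),
                _C3[2] * z * (xx - yy),
                _C3[3] * x * (xx - 3.0 * yy),
            ]
    return eg.concat(cols, axis=1)


def _contract_t(x: Tensor, degrees) -> Tensor:
    """Per-degree invariant contraction on traced tensors. (rows, n_deg)."""
    cols, off = [], 0
    for l in degrees:
        w = 2 * l + 1
        blk = x[:, off:off + w]
        cols.append(eg.sum_(blk * blk, axis=1, keepdims=True) * contraction_constant(l))
        off += w
    return eg.concat(cols, axis=1)


def _cutoff_t(r: Tensor, r_cut: float) -> Tensor:
    mask = Tensor((r.data <= r_cut).astype(np.float64))
    return 0.5 * (eg.cos(r * (np.pi / r_cut)) + 1.0) * mask


def _rbf_t(r: Tensor, cfg: ModelConfig) -> Tensor:
    mu = Tensor(cfg.rbf_centers[None, :])
    d = eg.exp(eg.neg(r)) - mu
    return eg.exp(eg.neg(cfg.rbf_gamma * d * d))


def _mlp2(x: Tensor, W1, b1, W2, b2) -> Tensor:
    return eg.matmul(eg.silu(eg.matmul(x, W1) + b1), W2) + b2


from functools import lru_cache


@lru_cache(maxsize=16)
def _degree_expand_index(degrees) -> np.ndarray:
    """Map EV component -> degree index, for broadcasting per-degree gains."""
    return np.concatenate([
        np.full(2 * l + 1, k, dtype=np.intp) for k, l in enumerate(degrees)
    ])


def _block_forward(f: Tensor, x: Tensor, geo, params, cfg: ModelConfig, t: int):
    """One Euclidean transformer block (self-attention + interaction)."""
    b = f"block{t}/"
    F = cfg.feature_dim
    f_att, x_att = _attention_only(f, x, geo, params, cfg, t)

    # interaction block: per-atom exchange between the two representations
    ui = _contract_t(x_att, cfg.degrees)
    y = eg.concat([f_att, ui], axis=1)
    ab = eg.silu(eg.matmul(y, params[b + "Wi"]) + params[b + "bi"])
    a = ab[:, :F]
    bl = ab[:, F:]
    f_new = f_att + a
    x_new = x_att + eg.take_cols(bl, _degree_expand_index(cfg.degrees)) * x_att
    return f_new, x_new


def _check_atomic_numbers(z, cfg: ModelConfig):
    bad = z[(z < 1) | (z > cfg.max_atomic_number)]
    if bad.size:
        raise ValueError(
            f"atomic number {int(bad[0])} outside the embedding table "
            f"(1..{cfg.max_atomic_number})"
        )


def _forward_t(pos: Tensor, system: AtomicSystem, nl: NeighborList,
               params, cfg: ModelConfig) -> Tuple[Tensor, Tensor]:
    """Traced forward pass: (total energy scalar, per-atom energies)."""
    z = system.atomic_numbers
    _check_atomic_numbers(z, cfg)
    n = system.n_atoms
    idx_i, idx_j = nl.idx_i, nl.idx_j
    shift_vec = Tensor(nl.displacements - (system.positions[idx_j] - system.positions[idx_i]))

    disp = eg.gather(pos, idx_j) - eg.gather(pos, idx_i) + shift_vec
    r2 = eg.sum_(disp * disp, axis=1, keepdims=True)
    r = eg.sqrt(r2)
    unit = disp / r
    phi = _cutoff_t(r, cfg.r_cut)
    g = _rbf_t(r, cfg)
    Y = _sph_columns(unit, cfg.degrees)

    f = eg.gather(params["embedding"], z - 1)
    if cfg.ev_init == "neighborhood":
        if cfg.mean_neighbors <= 0:
            raise ValueError("mean_neighbors must be positive for neighborhood EV init")
        x = eg.scatter_add(phi * Y, idx_i, n) * (1.0 / cfg.mean_neighbors)
    else:
        x = Tensor(np.zeros((n, cfg.ev_dim)))

    geo = (idx_i, idx_j, phi, g, Y, n)
    for t in range(cfg.blocks):
        f, x = _block_forward(f, x, geo, params, cfg, t)

    e = _mlp2(f, params["readout/W1"], params["readout/b1"],
              params["readout/W2"], params["readout/b2"])
    scale = eg.reshape(eg.gather(params["scale"], z - 1), (n, 1))
    shift = eg.reshape(eg.gather(params["shift"], z - 1), (n, 1))
    e_atoms = e * scale + shift
    return eg.sum_(e_atoms), e_atoms


# -- public operations -------------------------------------------------------

def embed(z, params, cfg: ModelConfig) -> FeatureState:
    """Initial invariant features: the embedding-table row of each element."""
    z = np.asarray(z, dtype=np.intp)
    _check_atomic_numbers(z, cfg)
    return FeatureState(params["embedding"].data[z - 1].copy())


def init_ev(system: AtomicSystem, nl: NeighborList, cfg: ModelConfig) -> EuclideanState:
    """Cutoff-modulated spherical-harmonic aggregate over each neighborhood."""
    if cfg.ev_init == "zeros":
        return EuclideanState(np.zeros((system.n_atoms, cfg.ev_dim)), cfg.degrees)
    if cfg.mean_neighbors <= 0:
        raise ValueError("mean_neighbors must be positive for neighborhood EV init")
    if nl.n_edges == 0:
        return EuclideanState(np.zeros((system.n_atoms, cfg.ev_dim)), cfg.degrees)
    unit = Tensor(nl.unit_vectors)
    phi = cutoff(nl.distances, cfg.r_cut)[:, None]
    Y = _sph_columns(unit, cfg.degrees).data
    out = np.zeros((system.n_atoms, cfg.ev_dim))
    np.add.at(out, nl.idx_i, phi * Y)
    return EuclideanState(out / cfg.mean_neighbors, cfg.degrees)


def cutoff(r, r_cut: float):
    """Cosine cutoff: 1 at r=0, 0 at and beyond r_cut, smooth in between."""
    r = np.asarray(r, dtype=np.float64)
    return np.where(r <= r_cut, 0.5 * (np.cos(np.pi * r / r_cut) + 1.0), 0.0)


def rbf(r, cfg: ModelConfig):
    """Gaussian radial basis on exp(-r): g_k = exp(-gamma (exp(-r)-mu_k)^2)."""
    r = np.asarray(r, dtype=np.float64)
    d = np.exp(-r)[..., None] - cfg.rbf_centers
    return np.exp(-cfg.rbf_gamma * d * d)


def filter_w(g, u, params, cfg: ModelConfig, block: int = 0):
    """Edge filter w = MLP_[F/4,F](u) + MLP_[F,F](g)."""
    b = f"block{block}/"
    gt, ut = Tensor(np.atleast_2d(g)), Tensor(np.atleast_2d(u))
    w = _mlp2(ut, params[b + "Wu1"], params[b + "bu1"],
              params[b + "Wu2"], params[b + "bu2"]) \
        + _mlp2(gt, params[b + "Wg1"], params[b + "bg1"],
                params[b + "Wg2"], params[b + "bg2"])
    return w.data


def attention_coeffs(f_i, f_j, w_ij, params, cfg: ModelConfig, block: int = 0):
    """Signed dot-product attention: per-head invariants and per-degree EV."""
    b = f"block{block}/"
    F, h, nd = cfg.feature_dim, cfg.heads, cfg.n_degrees
    f_i = np.atleast_2d(f_i)
    f_j = np.atleast_2d(f_j)
    w_ij = np.atleast_2d(w_ij)
    q = f_i @ params[b + "Qf"].data
    k = f_j @ params[b + "Kf"].data
    qe = f_i @ params[b + "Qe"].data
    ke = f_j @ params[b + "Ke"].data
    m = q * w_ij * k
    alpha = m.reshape(-1, h, F // h).sum(axis=2) / sqrt(F // h)
    me = qe * w_ij * ke
    alpha_l = me.reshape(-1, nd, F // nd).sum(axis=2) / sqrt(F // nd)
    return alpha, alpha_l


def attention_block(features: FeatureState, ev: EuclideanState, system: AtomicSystem,
                    nl: NeighborList, params, cfg: ModelConfig, block: int = 0):
    """Euclidean self-attention update of features and EV (with skips)."""
    f = Tensor(features.values)
    x = Tensor(ev.values)
    geo = _geometry(system, nl, cfg)
    f2, x2 = _attention_only(f, x, geo, params, cfg, block)
    return FeatureState(f2.data), EuclideanState(x2.data, cfg.degrees)


def interaction_block(features: FeatureState, ev: EuclideanState, params,
                      cfg: ModelConfig, block: int = 0):
    """Per-atom mixing of invariant and equivariant channels (with skips)."""
    b = f"block{block}/"
    F = cfg.feature_dim
    f = Tensor(features.values)
    x = Tensor(ev.values)
    ui = _contract_t(x, cfg.degrees)
    y = eg.concat([f, ui], axis=1)
    ab = eg.silu(eg.matmul(y, params[b + "Wi"]) + params[b + "bi"])
    a = ab[:, :F]
    bl = ab[:, F:]
    f_new = f + a
    x_new = x + eg.take_cols(bl, _degree_expand_index(cfg.degrees)) * x
    return FeatureState(f_new.data), EuclideanState(x_new.data, cfg.degrees)


def _geometry(system, nl, cfg):
    unit = Tensor(nl.unit_vectors)
    phi = Tensor(cutoff(nl.distances, cfg.r_cut)[:, None])
    g = Tensor(rbf(nl.distances, cfg))
    Y = _sph_columns(unit, cfg.degrees)
    return (nl.idx_i, nl.idx_j, phi, g, Y, system.n_atoms)


def _attention_only(f, x, geo, params, cfg, t):
    """Attention update without the interaction block (test hook)."""
    idx_i, idx_j, phi, g, Y, n = geo
    b = f"block{t}/"
    F, h, nd = cfg.feature_dim, cfg.heads, cfg.n_degrees
    xi = eg.gather(x, idx_i)
    xj = eg.gather(x, idx_j)
    u = _contract_t(xj - xi, cfg.degrees)
    w = _mlp2(u, params[b + "Wu1"], params[b + "bu1"],
              params[b + "Wu2"], params[b + "bu2"]) \
        + _mlp2(g, params[b + "Wg1"], params[b + "bg1"],
                params[b + "Wg2"], params[b + "bg2"])
    q = eg.gather(eg.matmul(f, params[b + "Qf"]), idx_i)
    k = eg.gather(eg.matmul(f, params[b + "Kf"]), idx_j)
    v = eg.gather(eg.matmul(f, params[b + "Vf"]), idx_j)
    E = q.shape[0]
    prod = eg.reshape(q * w * k, (E, h, F // h))
    alpha = eg.sum_(prod, axis=2, keepdims=True) * (1.0 / sqrt(F // h))
    msg = eg.reshape(alpha * eg.reshape(v, (E, h, F // h)), (E, F))
    f_att = f + eg.scatter_add(phi * msg, idx_i, n)
    qe = eg.gather(eg.matmul(f, params[b + "Qe"]), idx_i)
    ke = eg.gather(eg.matmul(f, params[b + "Ke"]), idx_j)
    prod_e = eg.reshape(qe * w * ke, (E, nd, F // nd))
    alpha_l = eg.sum_(prod_e, axis=2) * (1.0 / sqrt(F // nd))
    alpha_exp = eg.take_cols(alpha_l, _degree_expand_index(cfg.degrees))
    x_att = x + eg.scatter_add(phi * alpha_exp * Y, idx_i, n)
    return f_att, x_att


def forward_energy(system: AtomicSystem, params, cfg: ModelConfig):
    """Total potential energy (eV) and per-atom energies."""
    nl = build_neighbors(system, cfg.r_cut)
    pos = Tensor(system.positions)
    e_tot, e_atoms = _forward_t(pos, system, nl, params, cfg)
    return float(e_tot.data), e_atoms.data[:, 0].copy()


def forces(system: AtomicSystem, params, cfg: ModelConfig) -> np.ndarray:
    """F_i = -dE/dr_i, the exact reverse-mode gradient (eV/A)."""
    return energy_and_forces(system, params, cfg)[1]


def energy_and_forces(system: AtomicSystem, params, cfg: ModelConfig):
    nl = build_neighbors(system, cfg.r_cut)
    pos = Tensor(system.positions)
    e_tot, _ = _forward_t(pos, system, nl, params, cfg)
    grad = eg.backward(e_tot, pos)
    return float(e_tot.data), -grad.data


class NetworkPotential:
    """Potential-protocol adapter: energy_and_forces(system) -> (E, F)."""

    def __init__(self, params, cfg: ModelConfig):
        self.params = params
        self.cfg = cfg

    def energy_and_forces(self, system: AtomicSystem):
        return energy_and_forces(system, self.params, self.cfg)
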