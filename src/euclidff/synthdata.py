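"""Analytic toy potentials and labeled-dataset generators.

These stand in for quantum-chemistry reference data: every stage of the
library (training, MD, stability, observables, PES exploration) can be
exercised on configurations whose energies and forces are known in closed
form.  Lennard-Jones parameters default to argon (epsilon = 0.0103 eV,
sigma = 3.4 A) so that toy clusters live on physically plausible energy,
length and time scales; cluster datasets are sampled with thermostatted MD,
mimicking how reference datasets for learned force fields are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .graph import AtomicSystem
from .training import LabeledDataset

__all__ = [
    "LennardJones", "HarmonicMolecule", "DoubleWellMolecule",
    "lj_cluster_dataset", "harmonic_molecule", "perturbed_geometries",
    "lj_cluster_start", "potential_from_dict",
]

# argon-like defaults
LJ_EPSILON = 0.0103   # eV
LJ_SIGMA = 3.4        # A


class ToyPotential:
    """Analytic energy/force evaluator; forces are exact negative gradients."""

    def energy_and_forces(self, system: AtomicSystem) -> Tuple[float, np.ndarray]:
        raise NotImplementedError

    def check_forces(self, system: AtomicSystem, h: float = 1e-6,
                     rtol: float = 1e-6) -> float:
        """Max relative deviation of forces from central finite differences."""
        _, f = self.energy_and_forces(system)
        scale = max(np.abs(f).max(), 1e-10)
        worst = 0.0
        pos = system.positions
        for i in range(system.n_atoms):
            for k in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, k] += h
                pm[i, k] -= h
                ep, _ = self.energy_and_forces(system.with_positions(pp))
                em, _ = self.energy_and_forces(system.with_positions(pm))
                worst = max(worst, abs(-(ep - em) / (2 * h) - f[i, k]) / scale)
        if worst > rtol:
            raise AssertionError(f"force check failed: rel err {worst:.2e}")
        return worst


@dataclass
class LennardJones(ToyPotential):
    """Pairwise 4 eps ((sigma/r)^12 - (sigma/r)^6), all pairs (no cutoff)."""

    epsilon: float = LJ_EPSILON
    sigma: float = LJ_SIGMA

    def energy_and_forces(self, system: AtomicSystem):
        pos = system.positions
        n = system.n_atoms
        delta = pos[None, :, :] - pos[:, None, :]
        r2 = np.sum(delta * delta, axis=-1)
        np.fill_diagonal(r2, np.inf)
        s2 = self.sigma ** 2 / r2
        s6 = s2 ** 3
        s12 = s6 ** 2
        energy = 2.0 * self.epsilon * np.sum(s12 - s6)  # 4 eps, pairs counted twice
        # dE/dr_ij factor: 4 eps (-12 s12 + 6 s6)/r ; force on i sums over j
        coef = 24.0 * self.epsilon * (2.0 * s12 - s6) / r2
        forces = np.einsum("ij,ijk->ik", coef, -delta)
        return float(energy), forces

    @property
    def r_min(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma


def _check_connected(n_atoms: int, bonds) -> None:
    adj = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        for k in adj[stack.pop()]:
            if k not in seen:
                seen.add(k)
                stack.append(k)
    if len(seen) != n_atoms:
        raise ValueError("bond topology must be connected")


@dataclass
class HarmonicMolecule(ToyPotential):
    """Bonded springs: E = sum over bonds 1/2 k (r - r0)^2."""

    bonds: Tuple[Tuple[int, int], ...]
    k: np.ndarray          # eV/A^2, per bond (or scalar)
    r0: np.ndarray         # A, per bond (or scalar)
    n_atoms: int = 0

    def __post_init__(self):
        self.bonds = tuple((int(i), int(j)) for i, j in self.bonds)
        nb = len(self.bonds)
        self.k = np.broadcast_to(np.asarray(self.k, dtype=np.float64), (nb,)).copy()
        self.r0 = np.broadcast_to(np.asarray(self.r0, dtype=np.float64), (nb,)).copy()
        if self.n_atoms == 0:
            self.n_atoms = max(max(b) for b in self.bonds) + 1
        _check_connected(self.n_atoms, self.bonds)

    def energy_and_forces(self, system: AtomicSystem):
        pos = system.positions
        energy = 0.0
        forces = np.zeros_like(pos)
        for (i, j), k, r0 in zip(self.bonds, self.k, self.r0):
            d = pos[j] - pos[i]
            r = np.linalg.norm(d)
            energy += 0.5 * k * (r - r0) ** 2
            f = k * (r - r0) * d / r
            forces[i] += f
            forces[j] -= f
        return float(energy), forces


def harmonic_molecule(topology: Sequence[Tuple[int, int]], k, rest_lengths) -> HarmonicMolecule:
    """Spring "molecule" from a connected bond list (k in eV/A^2, r0 in A)."""
    return HarmonicMolecule(tuple(topology), k, rest_lengths)


@dataclass
class DoubleWellMolecule(ToyPotential):
    """Diatomic with a symmetric quartic double well in the bond length.

    E(r) = 16 V_b (r - a)^2 (r - b)^2 / (b - a)^4: minima at bond lengths a
    and b (E = 0), barrier height exactly V_b at the midpoint.
    """

    r_a: float = 1.2
    r_b: float = 2.0
    barrier: float = 0.5   # eV

    def energy_and_forces(self, system: AtomicSystem):
        if system.n_atoms != 2:
            raise ValueError("double-well molecule is diatomic")
        d = system.positions[1] - system.positions[0]
        r = np.linalg.norm(d)
        a, b = self.r_a, self.r_b
        c = 16.0 * self.barrier / (b - a) ** 4
        e = c * (r - a) ** 2 * (r - b) ** 2
        dedr = 2.0 * c * (r - a) * (r - b) * ((r - b) + (r - a))
        f = dedr * d / r
        return float(e), np.array([f, -f])


# -- dataset generation ------------------------------------------------------

def lj_cluster_start(n_atoms: int, seed: int = 0,
                     epsilon: float = LJ_EPSILON, sigma: float = LJ_SIGMA) -> AtomicSystem:
    """A relaxed Lennard-Jones cluster (argon atoms) to start sampling from."""
    from .explorer import relax  # local import: explorer depends on dynamics

    rng = np.random.default_rng(seed)
    pot = LennardJones(epsilon, sigma)
    pos = rng.normal(size=(n_atoms, 3)) * 0.45 * sigma
    system = AtomicSystem([18] * n_atoms, pos)
    minimum = relax(system, pot, f_max=1e-6, max_steps=5000)
    return minimum.system


def lj_cluster_dataset(n_atoms: int, n_samples: int, T_sample: float = 25.0,
                       seed: int = 0, dt: float = 2.0, n_equil: int = 500,
                       n_skip: int = 10, epsilon: float = LJ_EPSILON,
                       sigma: float = LJ_SIGMA) -> LabeledDataset:
    """Configurations from Langevin sampling on the LJ potential.

    Frames are decorrelated by ``n_skip`` MD steps; labels are the analytic
    energies and forces.  Deterministic per seed.
    """
    from .dynamics import MDConfig, init_velocities, run_md

    if n_atoms < 2:
        raise ValueError("need at least two atoms")
    pot = LennardJones(epsilon, sigma)
    system = lj_cluster_start(n_atoms, seed=seed, epsilon=epsilon, sigma=sigma)
    v0 = init_velocities(system, T_sample, mode="rescale_exact", seed=seed + 1)
    cfg = MDConfig(dt=dt, steps=n_equil + n_samples * n_skip, stride=n_skip,
                   integrator="langevin", temperature=T_sample, gamma=0.02,
                   seed=seed + 2)
    traj = run_md(system, pot, cfg, velocities=v0)
    frames = traj.frames[-n_samples:]
    systems, energies, forces = [], [], []
    for fr in frames:
        s = system.with_positions(fr.positions)
        e, f = pot.energy_and_forces(s)
        systems.append(s)
        energies.append(e)
        forces.append(f)
    return LabeledDataset(systems, np.array(energies), forces, "eV")


def potential_from_dict(spec: dict) -> ToyPotential:
    """Build a toy potential from a plain dict (CLI/config entry point)."""
    kind = spec.get("kind")
    if kind == "lennard_jones":
        return LennardJones(spec.get("epsilon", LJ_EPSILON), spec.get("sigma", LJ_SIGMA))
    if kind == "harmonic_molecule":
        return HarmonicMolecule(
            tuple(tuple(b) for b in spec["bonds"]), spec["k"], spec["r0"]
        )
    if kind == "double_well_molecule":
        return DoubleWellMolecule(
            spec.get("r_a", 1.2), spec.get("r_b", 2.0), spec.get("barrier", 0.5)
        )
    raise ValueError(f"unknown toy potential kind {kind!r}")


def perturbed_geometries(minimum: AtomicSystem, amplitude: float, n: int,
                         seed: int = 0) -> List[AtomicSystem]:
    """n copies with i.i.d. uniform per-coordinate displacements <= amplitude."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        d = rng.uniform(-amplitude, amplitude, size=minimum.positions.shape)
        out.append(minimum.with_positions(minimum.positions + d))
    return out
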