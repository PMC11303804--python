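"""Potential-energy-surface exploration by minima hopping.

The loop alternates short NVE "escape" runs started with thermal velocities
and quasi-Newton relaxations.  Newly relaxed geometries are identified
against the history by the RMSD minimized over proper rotations (centers of
mass removed, atom order fixed — permutation-equivalent copies of symmetric
clusters count as distinct, a documented limitation).  The MD temperature
and the acceptance window E_diff adapt to the visit history, and the largest
potential energy observed along an escape path between two minima serves as
an (upper-bound) transition-state estimate feeding the disconnectivity
graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .data import ACCEL_CONV
from .graph import AtomicSystem

__all__ = [
    "Minimum", "HoppingConfig", "MinimaHistory", "DisconnectivityGraph",
    "relax", "rmsd_so3", "escape", "hop", "disconnectivity", "RelaxationError",
]


class RelaxationError(RuntimeError):
    def __init__(self, message, system=None):
        super().__init__(message)
        self.system = system


@dataclass
class Minimum:
    system: AtomicSystem
    energy: float
    visits: int = 1
    discovery_index: int = 0


@dataclass
class HoppingConfig:
    T0: float = 1000.0          # K, initial escape temperature
    E_diff: float = 2.0         # eV, acceptance window
    beta_T: float = 1.05        # T multiplier on revisits (divisor on new)
    alpha_E: float = 1.05       # E_diff multiplier on reject (divisor on accept)
    escape_time: float = 1000.0  # fs (1 ps)
    dt: float = 0.5             # fs
    rmsd_threshold: float = 0.1  # A, identity criterion
    max_minima: int = 10
    max_hops: int = 200
    f_max: float = 1e-4         # eV/A, relaxation threshold
    seed: int = 0

    def __post_init__(self):
        for name in ("T0", "E_diff", "beta_T", "alpha_E", "escape_time", "dt",
                     "rmsd_threshold", "max_minima", "max_hops", "f_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MinimaHistory:
    minima: List[Minimum] = field(default_factory=list)
    # best (lowest) max-path-energy estimate per unordered minima pair
    transitions: Dict[Tuple[int, int], float] = field(default_factory=dict)
    temperatures: List[float] = field(default_factory=list)
    n_escapes: int = 0

    def energies(self) -> np.ndarray:
        return np.array([m.energy for m in self.minima])

    def record_transition(self, a: int, b: int, e_max: float):
        if a == b:
            return
        key = (min(a, b), max(a, b))
        if key not in self.transitions or e_max < self.transitions[key]:
            self.transitions[key] = e_max


def relax(system: AtomicSystem, potential, f_max: float = 1e-4,
          max_steps: int = 10_000) -> Minimum:
    """L-BFGS relaxation until the max per-atom force norm drops below f_max."""
    shape = system.positions.shape

    def objective(x):
        s = system.with_positions(x.reshape(shape))
        e, f = potential.energy_and_forces(s)
        return e, -f.ravel()

    x = system.positions.ravel().copy()
    done = 0
    while done < max_steps:
        chunk = min(200, max_steps - done)
        res = minimize(objective, x, jac=True, method="L-BFGS-B",
                       options={"maxiter": chunk, "gtol": 1e-14, "ftol": 1e-16})
        x = res.x
        done += max(res.nit, 1)
        e, f = potential.energy_and_forces(system.with_positions(x.reshape(shape)))
        if np.linalg.norm(f, axis=1).max() < f_max:
            return Minimum(system.with_positions(x.reshape(shape)), float(e))
        if res.nit == 0 and not res.success:
            break
    raise RelaxationError(
        f"relaxation did not reach |F|max < {f_max} within {max_steps} steps",
        system=system.with_positions(x.reshape(shape)),
    )


def rmsd_so3(a: AtomicSystem, b: AtomicSystem) -> float:
    """RMSD minimized over proper rotations after removing centers of mass.

    Atom order is fixed (no permutation search); compositions must match.
    """
    if a.n_atoms != b.n_atoms or np.any(a.atomic_numbers != b.atomic_numbers):
        raise ValueError("systems must share the atom count and element sequence")
    P = a.positions - a.center_of_mass()
    Q = b.positions - b.center_of_mass()
    # Kabsch with the proper-rotation (det +1) constraint
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (P @ R.T) - Q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def escape_steps(cfg: HoppingConfig) -> int:
    """Number of MD steps in one escape run (escape_time / dt)."""
    return max(1, int(round(cfg.escape_time / cfg.dt)))


def escape(minimum: Minimum, potential, T: float, cfg: HoppingConfig,
           seed: int = 0) -> Tuple[AtomicSystem, float]:
    """NVE escape run from a minimum; returns the end geometry and the
    maximum potential energy visited along the path."""
    from .dynamics import MDConfig, init_velocities, run_md

    system = minimum.system
    v0 = init_velocities(system, T, mode="rescale_exact", seed=seed)
    n_steps = escape_steps(cfg)
    md = MDConfig(dt=cfg.dt, steps=n_steps, stride=1, integrator="verlet", seed=seed)
    traj = run_md(system, potential, md, velocities=v0)
    e_max = float(traj.potential_energies.max())
    return system.with_positions(traj.frames[-1].positions), e_max


def hop(start: AtomicSystem, potential, cfg: HoppingConfig):
    """Minima-hopping loop: escape -> relax -> identity check -> acceptance.

    Returns (MinimaHistory, DisconnectivityGraph).  Fully seeded; the
    history is always consistent even if max_hops is exhausted early.
    """
    history = MinimaHistory()
    current = relax(start, potential, f_max=cfg.f_max)
    current_idx = 0
    history.minima.append(Minimum(current.system, current.energy, 1, 0))

    T = cfg.T0
    e_diff = cfg.E_diff
    rng = np.random.default_rng(cfg.seed)

    for _ in range(cfg.max_hops):
        if len(history.minima) >= cfg.max_minima:
            break
        history.temperatures.append(T)
        seed = int(rng.integers(2 ** 31 - 1))
        candidate_geo, e_path = escape(history.minima[current_idx], potential,
                                       T, cfg, seed=seed)
        history.n_escapes += 1
        try:
            cand = relax(candidate_geo, potential, f_max=cfg.f_max)
        except RelaxationError:
            T *= cfg.beta_T
            continue

        match = None
        for k, m in enumerate(history.minima):
            if rmsd_so3(m.system, cand.system) <= cfg.rmsd_threshold:
                match = k
                break

        if match == current_idx:
            # escape fell back into the same basin: raise the temperature
            history.minima[match].visits += 1
            T *= cfg.beta_T
            continue
        if match is not None:
            history.minima[match].visits += 1
            T *= cfg.beta_T
            cand_idx = match
        else:
            cand_idx = len(history.minima)
            history.minima.append(
                Minimum(cand.system, cand.energy, 1, cand_idx)
            )
            T /= cfg.beta_T
        history.record_transition(current_idx, cand_idx, e_path)

        if cand.energy - history.minima[current_idx].energy < e_diff:
            current_idx = cand_idx
            e_diff /= cfg.alpha_E
        else:
            e_diff *= cfg.alpha_E

    graph = disconnectivity(history)
    return history, graph


@dataclass
class DisconnectivityGraph:
    """Union-find merge tree of minima over an ascending energy grid."""

    energies: np.ndarray                     # minima energies
    merges: List[Tuple[float, int, int]]     # (level energy, root_a, root_b)
    levels: np.ndarray
    components_per_level: List[List[List[int]]]

    def n_components(self, level_energy: float) -> int:
        k = int(np.searchsorted(self.levels, level_energy, side="right")) - 1
        if k < 0:
            return len(self.energies)
        return len(self.components_per_level[k])

    def to_text(self) -> str:
        """Indented-text serialization of the merge tree."""
        lines = [f"minima: {len(self.energies)}"]
        for e, a, b in self.merges:
            lines.append(f"  merge at {e:+.6f} eV: {a} <- {b}")
        for lev, comps in zip(self.levels, self.components_per_level):
            groups = " | ".join(",".join(map(str, c)) for c in comps)
            lines.append(f"level {lev:+.6f} eV: {groups}")
        return "\n".join(lines)


def disconnectivity(history: MinimaHistory, level_spacing: float = 0.1) -> DisconnectivityGraph:
    """Merge minima below successive energy levels using recorded transitions.

    Disconnected components simply remain separate.  Merge energies can
    never drop below either endpoint minimum (the transition estimate is a
    path maximum).
    """
    energies = history.energies()
    n = len(energies)
    if n == 0:
        raise ValueError("empty history")
    pairs = sorted(history.transitions.items(), key=lambda kv: kv[1])

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    merges: List[Tuple[float, int, int]] = []
    for (a, b), e in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
            merges.append((float(e), min(ra, rb), max(ra, rb)))

    top = max([energies.max()] + [e for e, _, _ in merges])
    levels = np.arange(energies.min(), top + level_spacing, level_spacing)
    comps_per_level = []
    for lev in levels:
        p2 = list(range(n))

        def find2(i):
            while p2[i] != i:
                p2[i] = p2[p2[i]]
                i = p2[i]
            return i

        for (a, b), e in pairs:
            if e <= lev:
                ra, rb = find2(a), find2(b)
                if ra != rb:
                    p2[max(ra, rb)] = min(ra, rb)
        groups: Dict[int, List[int]] = {}
        for i in range(n):
            if energies[i] <= lev:
                groups.setdefault(find2(i), []).append(i)
        comps_per_level.append(sorted(groups.values()))
    return DisconnectivityGraph(energies, merges, levels, comps_per_level)
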