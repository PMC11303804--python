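"""Molecular dynamics: velocity initialization, integrators, thermostats.

Units: angstrom, femtosecond, eV, amu, kelvin.  A "potential" is any object
with ``energy_and_forces(system) -> (E, F)``; both the analytic toy
potentials and the learned network implement this protocol, so the same
integrators serve both.

Conventions pinned here:

* instantaneous temperature uses N_dof = 3N - 3 for isolated systems (the
  center-of-mass momentum is removed at initialization and conserved) and
  3N for periodic ones;
* the Langevin thermostat is the BAOAB splitting with friction gamma in
  1/fs; gamma = 0 recovers velocity Verlet exactly;
* the Nose-Hoover thermostat is a single (non-chained) thermostat with
  coupling time tau, default 100 dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .data import ACCEL_CONV, KB, KE_CONV, kinetic_energy
from .graph import AtomicSystem

__all__ = [
    "MDState", "Trajectory", "MDConfig", "MDInstabilityError",
    "init_velocities", "temperature", "verlet_step", "langevin_step",
    "nose_hoover_step", "run_md",
]


class MDInstabilityError(RuntimeError):
    """Non-finite state during integration; carries the failing step index."""

    def __init__(self, step: int, trajectory: Optional["Trajectory"] = None):
        super().__init__(f"non-finite forces or coordinates at MD step {step}")
        self.step = step
        self.trajectory = trajectory


@dataclass
class MDState:
    positions: np.ndarray    # n x 3, A
    velocities: np.ndarray   # n x 3, A/fs
    masses: np.ndarray       # amu
    time: float = 0.0        # fs
    potential_energy: float = 0.0
    forces: Optional[np.ndarray] = None
    # Nose-Hoover extended variables
    xi: float = 0.0
    eta: float = 0.0

    def copy(self) -> "MDState":
        return MDState(
            self.positions.copy(), self.velocities.copy(), self.masses,
            self.time, self.potential_energy,
            None if self.forces is None else self.forces.copy(),
            self.xi, self.eta,
        )

    def kinetic_energy(self) -> float:
        return kinetic_energy(self.velocities, self.masses)


@dataclass
class Trajectory:
    frames: List[MDState]
    dt: float
    stride: int
    thermostat: str
    seed: Optional[int] = None
    system: Optional[AtomicSystem] = None

    def __len__(self):
        return len(self.frames)

    @property
    def times(self):
        return np.array([f.time for f in self.frames])

    @property
    def positions(self):
        return np.stack([f.positions for f in self.frames])

    @property
    def velocities(self):
        return np.stack([f.velocities for f in self.frames])

    @property
    def potential_energies(self):
        return np.array([f.potential_energy for f in self.frames])

    @property
    def kinetic_energies(self):
        return np.array([f.kinetic_energy() for f in self.frames])

    @property
    def total_energies(self):
        return self.potential_energies + self.kinetic_energies

    def temperatures(self, periodic: bool = False):
        return np.array([temperature(f, periodic=periodic) for f in self.frames])


def n_dof(n_atoms: int, periodic: bool = False) -> int:
    if periodic:
        return 3 * n_atoms
    if n_atoms < 2:
        raise ValueError(
            "temperature of a single isolated atom is undefined "
            "(no internal degrees of freedom after COM removal)"
        )
    return 3 * n_atoms - 3


def temperature(state: MDState, periodic: bool = False) -> float:
    """Instantaneous temperature T = 2 KE / (N_dof k_B) in kelvin."""
    dof = n_dof(len(state.masses), periodic)
    return 2.0 * state.kinetic_energy() / (dof * KB)


def _remove_com_momentum(v, m):
    return v - (m @ v) / m.sum()


def _remove_angular_momentum(pos, v, m):
    """Project out rigid rotation about the center of mass."""
    com = m @ pos / m.sum()
    r = pos - com
    L = np.sum(m[:, None] * np.cross(r, v), axis=0)
    # inertia tensor
    r2 = np.sum(r * r, axis=1)
    I = np.einsum("a,abc->bc", m, r2[:, None, None] * np.eye(3) - r[:, :, None] * r[:, None, :])
    omega = np.linalg.lstsq(I, L, rcond=None)[0]
    return v - np.cross(omega, r)


def init_velocities(system: AtomicSystem, T_target: float, mode: str = "rescale_exact",
                    seed: int = 0, remove_rotation: bool = False) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the COM momentum removed.

    ``boltzmann_2T`` draws at twice the target temperature (the NVE-start
    convention: equipartition halves the temperature once the potential
    energy picks up its share).  ``rescale_exact`` draws at T and rescales
    so the instantaneous temperature matches T exactly.  With
    ``remove_rotation`` the rigid-rotation component is projected out as
    well (used when starting NVE runs exactly at a minimum).
    """
    if T_target < 0:
        raise ValueError("temperature must be non-negative")
    if mode not in ("boltzmann_2T", "rescale_exact"):
        raise ValueError("mode must be 'boltzmann_2T' or 'rescale_exact'")
    n = system.n_atoms
    m = system.masses
    if T_target == 0:
        return np.zeros((n, 3))
    rng = np.random.default_rng(seed)
    T_draw = 2.0 * T_target if mode == "boltzmann_2T" else T_target
    sigma = np.sqrt(KB * T_draw * ACCEL_CONV / m)[:, None]  # A/fs
    v = rng.normal(size=(n, 3)) * sigma
    v = _remove_com_momentum(v, m)
    if remove_rotation and not any(system.pbc):
        v = _remove_angular_momentum(system.positions, v, m)
    if mode == "rescale_exact":
        dof = n_dof(n, periodic=any(system.pbc))
        ke = kinetic_energy(v, m)
        v *= np.sqrt(0.5 * dof * KB * T_target / ke)
    return v


def _accelerations(forces, masses):
    return ACCEL_CONV * forces / masses[:, None]


def _eval(potential, system, positions, step):
    e, f = potential.energy_and_forces(system.with_positions(positions))
    if not (np.isfinite(e) and np.all(np.isfinite(f))):
        raise MDInstabilityError(step)
    return e, f


def verlet_step(state: MDState, potential, system: AtomicSystem, dt: float,
                step: int = 0) -> MDState:
    """One velocity-Verlet step; reuses the stored forces (one call/step)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.forces is None:
        state.potential_energy, state.forces = _eval(potential, system, state.positions, step)
    a = _accelerations(state.forces, state.masses)
    v_half = state.velocities + 0.5 * dt * a
    pos = state.positions + dt * v_half
    e, f = _eval(potential, system, pos, step)
    v = v_half + 0.5 * dt * _accelerations(f, state.masses)
    return MDState(pos, v, state.masses, state.time + dt, e, f, state.xi, state.eta)


def langevin_step(state: MDState, potential, system: AtomicSystem, dt: float,
                  T: float, gamma: float, rng: np.random.Generator,
                  step: int = 0) -> MDState:
    """BAOAB Langevin step targeting temperature T (gamma in 1/fs)."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if gamma == 0.0:
        return verlet_step(state, potential, system, dt, step)
    m = state.masses
    if state.forces is None:
        state.potential_energy, state.forces = _eval(potential, system, state.positions, step)
    v = state.velocities + 0.5 * dt * _accelerations(state.forces, m)   # B
    pos = state.positions + 0.5 * dt * v                                 # A
    c1 = np.exp(-gamma * dt)                                             # O
    sigma = np.sqrt((1.0 - c1 * c1) * KB * T * ACCEL_CONV / m)[:, None]
    v = c1 * v + sigma * rng.normal(size=v.shape)
    pos = pos + 0.5 * dt * v                                             # A
    e, f = _eval(potential, system, pos, step)
    v = v + 0.5 * dt * _accelerations(f, m)                              # B
    return MDState(pos, v, m, state.time + dt, e, f, state.xi, state.eta)


def nose_hoover_step(state: MDState, potential, system: AtomicSystem, dt: float,
                     T: float, tau: float, step: int = 0,
                     periodic: bool = False) -> MDState:
    """Single Nose-Hoover thermostat, coupling time tau (fs)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    m = state.masses
    dof = n_dof(len(m), periodic)
    Q = dof * KB * T * tau * tau   # thermostat "mass", eV fs^2
    if state.forces is None:
        state.potential_energy, state.forces = _eval(potential, system, state.positions, step)

    xi, eta = state.xi, state.eta
    ke = state.kinetic_energy()
    xi += 0.5 * dt * (2.0 * ke - dof * KB * T) / Q
    eta += 0.5 * dt * xi
    v = state.velocities * np.exp(-xi * 0.5 * dt)
    v = v + 0.5 * dt * _accelerations(state.forces, m)
    pos = state.positions + dt * v
    e, f = _eval(potential, system, pos, step)
    v = v + 0.5 * dt * _accelerations(f, m)
    v = v * np.exp(-xi * 0.5 * dt)
    ke = kinetic_energy(v, m)
    eta += 0.5 * dt * xi
    xi += 0.5 * dt * (2.0 * ke - dof * KB * T) / Q
    return MDState(pos, v, m, state.time + dt, e, f, xi, eta)


def nose_hoover_conserved(state: MDState, T: float, tau: float,
                          periodic: bool = False) -> float:
    """The extended-system invariant of the Nose-Hoover dynamics."""
    dof = n_dof(len(state.masses), periodic)
    Q = dof * KB * T * tau * tau
    return (
        state.potential_energy + state.kinetic_energy()
        + 0.5 * Q * state.xi ** 2 + dof * KB * T * state.eta
    )


@dataclass
class MDConfig:
    dt: float = 0.5                  # fs
    steps: int = 1000
    stride: int = 10
    integrator: str = "verlet"       # verlet | langevin | nose_hoover
    temperature: float = 300.0       # K (thermostats)
    gamma: float = 1e-3              # 1/fs (Langevin)
    tau: Optional[float] = None      # fs (Nose-Hoover), default 100 dt
    seed: int = 0

    def __post_init__(self):
        if self.integrator not in ("verlet", "langevin", "nose_hoover"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.dt <= 0 or self.steps < 1 or self.stride < 1:
            raise ValueError("dt, steps and stride must be positive")


def run_md(system: AtomicSystem, potential, cfg: MDConfig,
           velocities: Optional[np.ndarray] = None) -> Trajectory:
    """Integrate and sample every ``stride`` steps (frame 0 included).

    Instabilities raise :class:`MDInstabilityError` carrying the step index
    and the partial trajectory (consumed by the stability diagnostics).
    """
    m = system.masses
    if velocities is None:
        velocities = init_velocities(system, cfg.temperature,
                                     mode="boltzmann_2T", seed=cfg.seed)
    e0, f0 = potential.energy_and_forces(system)
    state = MDState(system.positions.copy(), np.array(velocities, dtype=np.float64),
                    m, 0.0, e0, f0)
    frames = [state.copy()]
    traj = Trajectory(frames, cfg.dt, cfg.stride, cfg.integrator, cfg.seed, system)
    rng = np.random.default_rng(cfg.seed + 1)
    periodic = any(system.pbc)
    try:
        for step in range(1, cfg.steps + 1):
            if cfg.integrator == "verlet":
                state = verlet_step(state, potential, system, cfg.dt, step)
            elif cfg.integrator == "langevin":
                state = langevin_step(state, potential, system, cfg.dt,
                                      cfg.temperature, cfg.gamma, rng, step)
            else:
                tau = cfg.tau if cfg.tau is not None else 100.0 * cfg.dt
                state = nose_hoover_step(state, potential, system, cfg.dt,
                                         cfg.temperature, tau, step, periodic)
            if step % cfg.stride == 0:
                frames.append(state.copy())
    except MDInstabilityError as err:
        raise MDInstabilityError(err.step, traj) from None
    return traj
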