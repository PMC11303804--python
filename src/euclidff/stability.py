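"""MD stability diagnostics.

A run is stable when (A) nothing dissociates non-physically — detected as a
temperature spike orders of magnitude above the target, or a non-finite
state — and (B) every bond length stays within 50% of its equilibrium value
at all sampled frames.  The stability coefficient c_s = n_s / n_tot is the
fraction of the run completed before the first violation (1 when none).

The temperature-spike factor (default 100x the target) and the covalent-
radius bond factor (default 1.25) are configurable pins; the 50% bond-
deviation criterion is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .data import covalent_radius
from .dynamics import Trajectory, temperature
from .graph import AtomicSystem

__all__ = [
    "BondSet", "StabilityReport", "detect_bonds", "check_stability",
    "stability_coefficient",
]

BOND_FACTOR = 1.25
SPIKE_FACTOR = 100.0
BOND_DEVIATION = 0.5


@dataclass
class BondSet:
    """Unordered bonded pairs with reference (equilibrium) lengths."""

    pairs: Tuple[Tuple[int, int], ...]
    reference_lengths: np.ndarray

    def __post_init__(self):
        self.reference_lengths = np.asarray(self.reference_lengths, dtype=np.float64)
        if np.any(self.reference_lengths <= 0):
            raise ValueError("reference bond lengths must be positive")

    def __len__(self):
        return len(self.pairs)


@dataclass
class StabilityReport:
    c_s: float
    n_s: int
    n_tot: int
    failure_mode: str = "none"          # none | A_dissociation | B_bond
    failing_step: Optional[int] = None
    failing_bond: Optional[Tuple[int, int]] = None

    def to_dict(self) -> dict:
        return {
            "c_s": self.c_s, "n_s": self.n_s, "n_tot": self.n_tot,
            "failure_mode": self.failure_mode,
            "failing_step": self.failing_step,
            "failing_bond": list(self.failing_bond) if self.failing_bond else None,
        }


def detect_bonds(system: AtomicSystem, factor: float = BOND_FACTOR) -> BondSet:
    """Pairs closer than ``factor`` x (sum of covalent radii); reference
    length = the initial distance."""
    pos = system.positions
    z = system.atomic_numbers
    pairs, lengths = [], []
    for i in range(system.n_atoms):
        for j in range(i + 1, system.n_atoms):
            d = float(np.linalg.norm(pos[j] - pos[i]))
            if d < factor * (covalent_radius(z[i]) + covalent_radius(z[j])):
                pairs.append((i, j))
                lengths.append(d)
    return BondSet(tuple(pairs), np.array(lengths))


def check_stability(traj: Trajectory, bonds: BondSet, T_target: float,
                    spike_factor: float = SPIKE_FACTOR,
                    bond_deviation: float = BOND_DEVIATION) -> StabilityReport:
    """Scan a trajectory for failure modes A and B (earliest frame wins)."""
    if len(traj.frames) == 0:
        raise ValueError("empty trajectory")
    n_tot = (len(traj.frames) - 1) * traj.stride
    if n_tot == 0:
        n_tot = 1
    periodic = traj.system is not None and any(traj.system.pbc)
    idx = np.array(bonds.pairs, dtype=np.intp).reshape(-1, 2)
    for k, frame in enumerate(traj.frames):
        step = k * traj.stride
        finite = np.all(np.isfinite(frame.positions)) and np.all(np.isfinite(frame.velocities))
        if not finite or temperature(frame, periodic=periodic) > spike_factor * T_target:
            return StabilityReport(
                c_s=step / n_tot, n_s=step, n_tot=n_tot,
                failure_mode="A_dissociation", failing_step=step,
            )
        if len(idx):
            d = np.linalg.norm(
                frame.positions[idx[:, 1]] - frame.positions[idx[:, 0]], axis=1
            )
            dev = np.abs(d - bonds.reference_lengths) / bonds.reference_lengths
            worst = int(np.argmax(dev))
            if dev[worst] > bond_deviation:
                return StabilityReport(
                    c_s=step / n_tot, n_s=step, n_tot=n_tot,
                    failure_mode="B_bond", failing_step=step,
                    failing_bond=bonds.pairs[worst],
                )
    return StabilityReport(c_s=1.0, n_s=n_tot, n_tot=n_tot)


def stability_coefficient(n_s: int, n_tot: int) -> float:
    """c_s = n_s / n_tot, the completed fraction of the run."""
    if n_tot <= 0:
        raise ValueError("n_tot must be positive")
    if not 0 <= n_s <= n_tot:
        raise ValueError("need 0 <= n_s <= n_tot")
    return n_s / n_tot
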