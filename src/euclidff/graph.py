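"""Atomic systems, neighborhoods and displacement geometry.

Coordinates are Cartesian angstrom throughout.  Periodic systems use the
minimum-image convention; cutoffs beyond half the smallest cell height are
refused rather than silently enumerating further images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data import atomic_mass

__all__ = ["AtomicSystem", "NeighborList", "build_neighbors", "mean_neighbor_count"]


@dataclass
class AtomicSystem:
    """Atomic numbers + Cartesian positions (+ optional periodic cell)."""

    atomic_numbers: np.ndarray
    positions: np.ndarray
    cell: Optional[np.ndarray] = None
    pbc: tuple = (False, False, False)
    masses: Optional[np.ndarray] = None

    def __post_init__(self):
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.intp)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.atomic_numbers.ndim != 1 or len(self.atomic_numbers) < 1:
            raise ValueError("need at least one atom")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be positive")
        if self.positions.shape != (len(self.atomic_numbers), 3):
            raise ValueError("positions must be n x 3")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if isinstance(self.pbc, bool):
            self.pbc = (self.pbc,) * 3
        self.pbc = tuple(bool(p) for p in self.pbc)
        if any(self.pbc):
            if self.cell is None:
                raise ValueError("cell required when pbc is set")
            self.cell = np.asarray(self.cell, dtype=np.float64)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be 3 x 3")
        if self.masses is None:
            self.masses = np.array([atomic_mass(z) for z in self.atomic_numbers])
        else:
            self.masses = np.asarray(self.masses, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return len(self.atomic_numbers)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            self.atomic_numbers.copy(), self.positions.copy(),
            None if self.cell is None else self.cell.copy(),
            self.pbc, self.masses.copy(),
        )

    def with_positions(self, positions) -> "AtomicSystem":
        new = self.copy()
        new.positions = np.asarray(positions, dtype=np.float64).reshape(-1, 3)
        return new

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.positions / self.masses.sum()


@dataclass
class NeighborList:
    """Directed edges (i, j) with displacement r_j - r_i (minimum image)."""

    idx_i: np.ndarray
    idx_j: np.ndarray
    displacements: np.ndarray  # E x 3, r_ij = r_j - r_i (+ periodic shift)
    distances: np.ndarray      # E
    r_cut: float

    @property
    def n_edges(self) -> int:
        return len(self.idx_i)

    @property
    def unit_vectors(self) -> np.ndarray:
        return self.displacements / self.distances[:, None]


def _cell_heights(cell: np.ndarray) -> np.ndarray:
    """Perpendicular heights of the cell along its three axes."""
    inv = np.linalg.inv(cell)
    return 1.0 / np.linalg.norm(inv, axis=0)


def build_neighbors(system: AtomicSystem, r_cut: float) -> NeighborList:
    """Exact cutoff-sphere neighbor list, lexicographic (i, j) edge order."""
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    pos = system.positions
    n = system.n_atoms
    delta = pos[None, :, :] - pos[:, None, :]  # delta[i, j] = r_j - r_i
    if any(system.pbc):
        heights = _cell_heights(system.cell)
        for ax, per in enumerate(system.pbc):
            if per and r_cut >= 0.5 * heights[ax]:
                raise ValueError(
                    f"r_cut={r_cut} exceeds half the cell height "
                    f"{heights[ax]:.4f} along axis {ax}: minimum-image "
                    "convention invalid"
                )
        frac = delta @ np.linalg.inv(system.cell)
        for ax, per in enumerate(system.pbc):
            if per:
                frac[..., ax] -= np.round(frac[..., ax])
        delta = frac @ system.cell
    dist = np.linalg.norm(delta, axis=-1)
    mask = (dist <= r_cut) & ~np.eye(n, dtype=bool)
    idx_i, idx_j = np.nonzero(mask)  # row-major == lexicographic (i, j)
    return NeighborList(
        idx_i=idx_i, idx_j=idx_j,
        displacements=delta[idx_i, idx_j],
        distances=dist[idx_i, idx_j],
        r_cut=float(r_cut),
    )


def mean_neighbor_count(dataset: Sequence[AtomicSystem], r_cut: float) -> float:
    """Dataset-global mean: total directed edges / total atoms."""
    systems = list(dataset)
    if not systems:
        raise ValueError("dataset must be non-empty")
    edges = sum(build_neighbors(s, r_cut).n_edges for s in systems)
    atoms = sum(s.n_atoms for s in systems)
    return edges / atoms
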