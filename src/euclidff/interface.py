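"""File formats: extended XYZ frames, model checkpoints, report files.

The extended-XYZ dialect written here follows the de-facto standard: a
``Properties=`` comment-line descriptor, optional ``Lattice`` (row-major 9
floats), optional ``energy``; per-atom columns for species, positions and
optional forces/velocities.  Floats are written with 12 significant digits
and round-trip losslessly at that precision.  Atom indexing is 0-based
internally (the CLI accepts 1-based selections and converts).
"""

from __future__ import annotations

import json
import shlex
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data import atomic_number, symbol
from .engine import Tensor
from .graph import AtomicSystem
from .network import ModelConfig

__all__ = [
    "Frame", "read_extxyz", "write_extxyz", "save_checkpoint",
    "load_checkpoint", "CheckpointError", "ExtxyzError",
]

CHECKPOINT_VERSION = 1


class ExtxyzError(ValueError):
    pass


class CheckpointError(RuntimeError):
    pass


@dataclass
class Frame:
    system: AtomicSystem
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    velocities: Optional[np.ndarray] = None


def _parse_comment(line: str) -> Dict[str, str]:
    out = {}
    for token in shlex.split(line):
        if "=" in token:
            k, v = token.split("=", 1)
            out[k] = v
    return out


def _parse_properties(spec: str):
    fields = spec.split(":")
    if len(fields) % 3:
        raise ExtxyzError(f"malformed Properties descriptor {spec!r}")
    cols = []
    for k in range(0, len(fields), 3):
        name, kind, width = fields[k], fields[k + 1], int(fields[k + 2])
        cols.append((name, kind, width))
    return cols


def read_extxyz(path) -> List[Frame]:
    """Parse an extended-XYZ file into frames (0-based internal indexing)."""
    frames = []
    lines = Path(path).read_text().splitlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].split()[0])
        except (ValueError, IndexError):
            raise ExtxyzError(f"line {ln + 1}: expected an atom count")
        if ln + 1 + n >= len(lines) + 1 and n > 0:
            raise ExtxyzError(f"line {ln + 1}: truncated frame ({n} atoms declared)")
        meta = _parse_comment(lines[ln + 1])
        props = _parse_properties(meta.get("Properties", "species:S:1:pos:R:3"))
        cell = None
        pbc = (False, False, False)
        if "Lattice" in meta:
            vals = [float(v) for v in meta["Lattice"].split()]
            if len(vals) != 9:
                raise ExtxyzError(f"line {ln + 2}: Lattice needs 9 floats")
            cell = np.array(vals).reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in meta:
            pbc = tuple(t in ("T", "True", "1") for t in meta["pbc"].split())
        energy = float(meta["energy"]) if "energy" in meta else None

        species, arrays = [], {name: [] for name, _, _ in props if name != "species"}
        for a in range(n):
            row = lines[ln + 2 + a].split()
            want = sum(w for _, _, w in props)
            if len(row) < want:
                raise ExtxyzError(
                    f"line {ln + 3 + a}: expected {want} columns, got {len(row)}"
                )
            off = 0
            for name, kind, width in props:
                chunk = row[off:off + width]
                off += width
                if name == "species":
                    species.append(chunk[0])
                else:
                    arrays[name].append([float(v) for v in chunk])
        z = [atomic_number(s) if not s.isdigit() else int(s) for s in species]
        pos = np.array(arrays.get("pos"), dtype=np.float64)
        system = AtomicSystem(z, pos, cell=cell, pbc=pbc)
        frames.append(Frame(
            system=system,
            energy=energy,
            forces=np.array(arrays["forces"]) if "forces" in arrays else None,
            velocities=np.array(arrays["velocities"]) if "velocities" in arrays else None,
        ))
        ln += 2 + n
    return frames


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_extxyz(path, frames: List[Frame]) -> None:
    """Write frames in the extended-XYZ dialect (deterministic bytes)."""
    out = []
    for fr in frames:
        s = fr.system
        props = "species:S:1:pos:R:3"
        if fr.velocities is not None:
            props += ":velocities:R:3"
        if fr.forces is not None:
            props += ":forces:R:3"
        comment = [f"Properties={props}"]
        if s.cell is not None:
            flat = " ".join(_fmt(v) for v in s.cell.ravel())
            comment.append(f'Lattice="{flat}"')
            comment.append("pbc=" + " ".join("T" if p else "F" for p in s.pbc))
        if fr.energy is not None:
            comment.append(f"energy={_fmt(fr.energy)}")
        out.append(str(s.n_atoms))
        out.append(" ".join(comment))
        for a in range(s.n_atoms):
            row = [symbol(int(s.atomic_numbers[a]))]
            row += [_fmt(v) for v in s.positions[a]]
            if fr.velocities is not None:
                row += [_fmt(v) for v in fr.velocities[a]]
            if fr.forces is not None:
                row += [_fmt(v) for v in fr.forces[a]]
            out.append(" ".join(row))
    Path(path).write_text("\n".join(out) + "\n")


def trajectory_frames(traj) -> List[Frame]:
    """Convert a Trajectory to writable frames (positions, velocities, E)."""
    sys0 = traj.system
    return [
        Frame(
            system=sys0.with_positions(f.positions),
            energy=f.potential_energy,
            velocities=f.velocities,
        )
        for f in traj.frames
    ]


def save_trajectory(traj, path) -> None:
    """Compact binary trajectory store (npz): positions, velocities,
    energies, times plus the system definition."""
    s = traj.system
    np.savez_compressed(
        path,
        positions=traj.positions, velocities=traj.velocities,
        potential_energies=traj.potential_energies, times=traj.times,
        atomic_numbers=s.atomic_numbers, masses=s.masses,
        cell=s.cell if s.cell is not None else np.zeros((0, 3)),
        pbc=np.array(s.pbc), dt=traj.dt, stride=traj.stride,
        thermostat=np.frombuffer(traj.thermostat.encode(), dtype=np.uint8),
    )


def load_trajectory(path):
    """Round-trips :func:`save_trajectory`."""
    from .dynamics import MDState, Trajectory

    with np.load(path) as d:
        cell = d["cell"] if d["cell"].size else None
        system = AtomicSystem(d["atomic_numbers"], d["positions"][0],
                              cell=cell, pbc=tuple(bool(p) for p in d["pbc"]),
                              masses=d["masses"])
        frames = [
            MDState(p, v, system.masses, float(t), float(e))
            for p, v, t, e in zip(d["positions"], d["velocities"],
                                  d["times"], d["potential_energies"])
        ]
        return Trajectory(frames, float(d["dt"]), int(d["stride"]),
                          bytes(d["thermostat"]).decode(), system=system)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(params: Dict[str, Tensor], cfg: ModelConfig, path) -> None:
    """Versioned container (npz): config JSON + named parameter arrays."""
    arrays = {f"param:{k}": p.data for k, p in params.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps({"version": CHECKPOINT_VERSION, "config": cfg.to_dict()}).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> Tuple[Dict[str, Tensor], ModelConfig]:
    """Load a checkpoint; bit-exact parameter round trip."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != CHECKPOINT_VERSION:
                raise CheckpointError(
                    f"checkpoint version {meta.get('version')} != "
                    f"{CHECKPOINT_VERSION}: migration required"
                )
            params = {
                k[len("param:"):]: Tensor(data[k])
                for k in data.files if k.startswith("param:")
            }
            cfg = ModelConfig.from_dict(meta["config"])
    except CheckpointError:
        raise
    except Exception as err:
        raise CheckpointError(f"cannot read checkpoint {path}: {err}") from err
    return params, cfg
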