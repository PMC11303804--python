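"""Physical observables from trajectories and potentials.

Covers the standard MD analysis toolbox: radial distribution functions,
vibrational power spectra from the velocity autocorrelation function,
radius of gyration, end-to-end distances, backbone torsions, and harmonic
normal-mode analysis with zero-point energies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .data import ACCEL_CONV, C_LIGHT_CM_FS, HBAR, KB
from .dynamics import Trajectory
from .graph import AtomicSystem

__all__ = [
    "Spectrum", "NormalModeResult", "rdf", "vacf_spectrum",
    "radius_of_gyration", "end_to_end_distance", "dihedral",
    "normal_modes", "zpe_temperature",
]


@dataclass
class Spectrum:
    wavenumbers: np.ndarray      # cm^-1
    intensity: np.ndarray        # arbitrary units
    window: str = "hann"
    n_pad: int = 0

    def peak_wavenumber(self) -> float:
        return float(self.wavenumbers[np.argmax(self.intensity)])

    @property
    def bin_width(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])


@dataclass
class NormalModeResult:
    frequencies: np.ndarray          # cm^-1, sorted ascending (vibrational)
    modes: np.ndarray                # mass-weighted eigenvectors, columns
    zpe: float                       # eV
    imaginary_frequencies: np.ndarray  # cm^-1 magnitudes of unstable modes

    @property
    def is_minimum(self) -> bool:
        return self.imaginary_frequencies.size == 0


def rdf(traj: Trajectory, pair_selection: Optional[Tuple[Sequence[int], Sequence[int]]] = None,
        r_max: float = 10.0, n_bins: int = 100):
    """Radial distribution function g(r).

    Periodic systems: shell counts normalized by the ideal-gas expectation
    at the system's density (minimum-image distances; r_max must not exceed
    half the smallest cell height).  Isolated systems: the normalized
    pair-distance density (integrates to 1 over the histogram range).

    Returns (bin_centers, g).
    """
    system = traj.system
    if system is None:
        raise ValueError("trajectory carries no system metadata")
    n = system.n_atoms
    if pair_selection is None:
        sel_a = sel_b = np.arange(n)
    else:
        sel_a = np.asarray(pair_selection[0], dtype=np.intp)
        sel_b = np.asarray(pair_selection[1], dtype=np.intp)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty pair selection")
    periodic = any(system.pbc)
    if periodic:
        inv = np.linalg.inv(system.cell)
        heights = 1.0 / np.linalg.norm(inv, axis=0)
        if r_max > 0.5 * heights.min():
            raise ValueError("r_max exceeds half the smallest cell height")

    edges = np.linspace(0.0, r_max, n_bins + 1)
    counts = np.zeros(n_bins)
    n_pairs_total = 0
    for frame in traj.frames:
        pos = frame.positions
        delta = pos[sel_b][None, :, :] - pos[sel_a][:, None, :]
        if periodic:
            frac = delta @ inv
            frac -= np.round(frac)
            delta = frac @ system.cell
        dist = np.linalg.norm(delta, axis=-1)
        same = sel_a[:, None] == sel_b[None, :]
        d = dist[~same]
        counts += np.histogram(d, bins=edges)[0]
        n_pairs_total += d.size
    centers = 0.5 * (edges[1:] + edges[:-1])
    if periodic:
        volume = abs(np.linalg.det(system.cell))
        shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        rho_pairs = n_pairs_total / len(traj.frames) / volume
        ideal = shell * rho_pairs * len(traj.frames)
        g = np.divide(counts, ideal, out=np.zeros_like(counts), where=ideal > 0)
    else:
        # normalized pair-distance density
        width = edges[1] - edges[0]
        g = counts / max(n_pairs_total, 1) / width
    return centers, g


def vacf_spectrum(traj: Trajectory, mass_weighted: bool = False) -> Spectrum:
    """Vibrational power spectrum: windowed FFT of <v(0).v(t)>.

    The autocorrelation averages over atoms, Cartesian components and time
    origins (computed via FFT); a Hann window plus zero-padding to the next
    power of two precedes the transform.  The wavenumber axis is cm^-1.
    """
    if len(traj.frames) < 2:
        raise ValueError("need at least two frames")
    v = traj.velocities  # (T, n, 3)
    T_frames = v.shape[0]
    dt = traj.dt * traj.stride
    sig = v.reshape(T_frames, -1)
    if mass_weighted:
        w = np.sqrt(np.repeat(traj.frames[0].masses, 3))
        sig = sig * w
    # FFT-based autocorrelation per channel, averaged
    n_fft = 2 * T_frames
    S = np.fft.rfft(sig, n=n_fft, axis=0)
    acf = np.fft.irfft(S * S.conj(), n=n_fft, axis=0)[:T_frames].real
    norm = (T_frames - np.arange(T_frames))[:, None]
    acf = (acf / norm).sum(axis=1)
    window = np.hanning(2 * T_frames)[T_frames:]
    acf_w = acf * window
    n_pad = 1 << int(np.ceil(np.log2(2 * T_frames)))
    power = np.abs(np.fft.rfft(acf_w, n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=dt)          # 1/fs
    wavenumbers = freqs / C_LIGHT_CM_FS            # cm^-1
    return Spectrum(wavenumbers, power, "hann", n_pad)


def radius_of_gyration(frame_positions: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance from the center of mass (A)."""
    pos = np.asarray(frame_positions, dtype=np.float64)
    m = np.asarray(masses, dtype=np.float64)
    com = m @ pos / m.sum()
    return float(np.sqrt(np.sum(m * np.sum((pos - com) ** 2, axis=1)) / m.sum()))


def end_to_end_distance(frame_positions: np.ndarray, i: int, j: int) -> float:
    pos = np.asarray(frame_positions, dtype=np.float64)
    n = len(pos)
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range (n={n})")
    return float(np.linalg.norm(pos[j] - pos[i]))


def dihedral(frame_positions: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Signed torsion angle in degrees, IUPAC convention, range (-180, 180]."""
    pos = np.asarray(frame_positions, dtype=np.float64)
    if len({a, b, c, d}) != 4:
        raise ValueError("need four distinct atom indices")
    b1 = pos[b] - pos[a]
    b2 = pos[c] - pos[b]
    b3 = pos[d] - pos[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nrm = np.linalg.norm
    if nrm(n1) < 1e-10 or nrm(n2) < 1e-10:
        raise ValueError("collinear atoms: torsion undefined")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / nrm(b2))
    ang = np.degrees(np.arctan2(y, x))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def normal_modes(system: AtomicSystem, potential, displacement: float = 1e-3,
                 imag_tol: float = 1.0) -> NormalModeResult:
    """Harmonic analysis at a relaxed geometry.

    The Hessian comes from central finite differences of the analytic
    forces; after mass weighting, rigid translations and rotations are
    projected out and the remaining eigenvalues give harmonic wavenumbers
    and the zero-point energy ZPE = 1/2 hbar sum(omega).  Eigenvalues more
    negative than the tolerance are reported as imaginary frequencies.
    """
    n = system.n_atoms
    pos = system.positions
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for k in range(3):
            pp, pm = pos.copy(), pos.copy()
            pp[i, k] += displacement
            pm[i, k] -= displacement
            _, fp = potential.energy_and_forces(system.with_positions(pp))
            _, fm = potential.energy_and_forces(system.with_positions(pm))
            H[:, 3 * i + k] = -(fp - fm).ravel() / (2 * displacement)
    H = 0.5 * (H + H.T)
    m = np.repeat(system.masses, 3)
    Hmw = H / np.sqrt(np.outer(m, m))

    # rigid-motion basis (mass-weighted translations + rotations)
    com = system.center_of_mass()
    r = pos - com
    basis = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        basis.append((t * np.sqrt(system.masses)[:, None]).ravel())
    for axis in np.eye(3):
        rot = np.cross(axis, r)
        basis.append((rot * np.sqrt(system.masses)[:, None]).ravel())
    B = np.array(basis).T
    Q, Rfac = np.linalg.qr(B)
    keep = np.abs(np.diag(Rfac)) > 1e-8
    Q = Q[:, keep]
    P = np.eye(3 * n) - Q @ Q.T
    Hp = P @ Hmw @ P

    evals, evecs = np.linalg.eigh(Hp)
    # drop the projected-out rigid modes (eigenvalues pinned to ~0)
    order = np.argsort(np.abs(evals))
    rigid = order[: Q.shape[1]]
    vib_mask = np.ones(3 * n, dtype=bool)
    vib_mask[rigid] = False
    lam = evals[vib_mask]
    vecs = evecs[:, vib_mask]

    # eigenvalues eV/(A^2 amu) -> omega in 1/fs
    omega2 = lam * ACCEL_CONV
    tol_omega2 = (imag_tol * 2 * np.pi * C_LIGHT_CM_FS) ** 2
    imag = omega2 < -tol_omega2
    omega = np.sqrt(np.clip(omega2, 0.0, None))
    wn = omega / (2 * np.pi * C_LIGHT_CM_FS)
    wn_imag = np.sqrt(np.clip(-omega2[imag], 0.0, None)) / (2 * np.pi * C_LIGHT_CM_FS)
    zpe = 0.5 * HBAR * omega[~imag].sum()
    srt = np.argsort(wn[~imag])
    return NormalModeResult(
        frequencies=wn[~imag][srt],
        modes=vecs[:, ~imag][:, srt],
        zpe=float(zpe),
        imaginary_frequencies=np.sort(wn_imag)[::-1],
    )


def zpe_temperature(E_zpe: float, n_atoms: int) -> float:
    """Temperature equivalent of a zero-point energy: T = E / ((3n-6) k_B).

    Uses the 3N-6 vibrational-mode count of a nonlinear molecule.
    """
    if n_atoms < 3:
        raise ValueError("nonlinear-molecule convention needs n_atoms >= 3")
    return E_zpe / ((3 * n_atoms - 6) * KB)
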