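"""Physical constants, element tables and unit conversions.

Internal unit system: angstrom, femtosecond, electron-volt, atomic mass unit,
kelvin.  In these units an acceleration F/m picks up the factor
``ACCEL_CONV`` below (i.e. 1 eV/(A*amu) = 9.648533212e-3 A/fs^2, stated to
10 significant digits).
"""

from __future__ import annotations

import numpy as np

# Boltzmann constant, eV/K
KB = 8.617333262e-5
# 1 eV/(A*amu) in A/fs^2
ACCEL_CONV = 9.648533212e-3
# kinetic energy: (amu * A^2/fs^2) -> eV is 1/ACCEL_CONV
KE_CONV = 1.0 / ACCEL_CONV
# reduced Planck constant, eV*fs
HBAR = 0.6582119569
# speed of light, cm/fs
C_LIGHT_CM_FS = 2.99792458e-5
# 1 eV in kcal/mol (pinned conversion used across dataset I/O)
EV_TO_KCALMOL = 23.0609

# standard atomic weights (amu), Z = 1..86
_MASSES = [
    1.008, 4.0026, 6.94, 9.0122, 10.81, 12.011, 14.007, 15.999, 18.998,
    20.180, 22.990, 24.305, 26.982, 28.085, 30.974, 32.06, 35.45, 39.948,
    39.098, 40.078, 44.956, 47.867, 50.942, 51.996, 54.938, 55.845, 58.933,
    58.693, 63.546, 65.38, 69.723, 72.630, 74.922, 78.971, 79.904, 83.798,
    85.468, 87.62, 88.906, 91.224, 92.906, 95.95, 97.0, 101.07, 102.91,
    106.42, 107.87, 112.41, 114.82, 118.71, 121.76, 127.60, 126.90, 131.29,
    132.91, 137.33, 138.91, 140.12, 140.91, 144.24, 145.0, 150.36, 151.96,
    157.25, 158.93, 162.50, 164.93, 167.26, 168.93, 173.05, 174.97, 178.49,
    180.95, 183.84, 186.21, 190.23, 192.22, 195.08, 196.97, 200.59, 204.38,
    207.2, 208.98, 209.0, 210.0, 222.0,
]

# Cordero covalent radii (angstrom), Z = 1..86 (sp3 values where applicable)
_COVALENT_RADII = [
    0.31, 0.28, 1.28, 0.96, 0.84, 0.76, 0.71, 0.66, 0.57, 0.58, 1.66, 1.41,
    1.21, 1.11, 1.07, 1.05, 1.02, 1.06, 2.03, 1.76, 1.70, 1.60, 1.53, 1.39,
    1.39, 1.32, 1.26, 1.24, 1.32, 1.22, 1.22, 1.20, 1.19, 1.20, 1.20, 1.16,
    2.20, 1.95, 1.90, 1.75, 1.64, 1.54, 1.47, 1.46, 1.42, 1.39, 1.45, 1.44,
    1.42, 1.39, 1.39, 1.38, 1.39, 1.40, 2.44, 2.15, 2.07, 2.04, 2.03, 2.01,
    1.99, 1.98, 1.98, 1.96, 1.94, 1.92, 1.92, 1.89, 1.90, 1.87, 1.87, 1.75,
    1.70, 1.62, 1.51, 1.44, 1.41, 1.36, 1.36, 1.32, 1.45, 1.46, 1.48, 1.40,
    1.50, 1.50,
]

_SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
]

_Z_OF = {s: i + 1 for i, s in enumerate(_SYMBOLS)}


def atomic_mass(z: int) -> float:
    if not 1 <= z <= len(_MASSES):
        raise ValueError(f"no mass tabulated for atomic number {z}")
    return _MASSES[z - 1]


def covalent_radius(z: int) -> float:
    if not 1 <= z <= len(_COVALENT_RADII):
        raise ValueError(f"no covalent radius tabulated for atomic number {z}")
    return _COVALENT_RADII[z - 1]


def symbol(z: int) -> str:
    if not 1 <= z <= len(_SYMBOLS):
        raise ValueError(f"no symbol for atomic number {z}")
    return _SYMBOLS[z - 1]


def atomic_number(sym: str) -> int:
    try:
        return _Z_OF[sym.capitalize() if len(sym) > 1 else sym.upper()]
    except KeyError:
        raise ValueError(f"unknown element symbol {sym!r}") from None


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Kinetic energy in eV for velocities in A/fs, masses in amu."""
    return 0.5 * KE_CONV * float(np.sum(masses[:, None] * velocities ** 2))
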