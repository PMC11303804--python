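"""Real spherical harmonics, Wigner rotations and Clebsch-Gordan machinery.

Conventions (pinned; any self-consistent choice works, this one is asserted
throughout the test suite):

* real, orthonormal spherical harmonics over the unit sphere,
  components ordered degree-major with m = -l ... l;
* the degree-1 components are proportional to (y, z, x);
* the per-degree invariant contraction of a spherical tensor is
  ``sum_m x_lm**2 / sqrt(2l+1)`` — the projection of the tensor product
  ``x (x) x`` onto total degree L=0, up to this fixed per-degree constant.

The full Clebsch-Gordan table exists only as a brute-force cross-check: the
production model never performs tensor-product convolutions.
"""

from __future__ import annotations

from functools import lru_cache
from math import factorial, pi, sqrt

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "SphericalTensor", "real_sph_harm", "wigner_d", "cg_table", "CGTable",
    "degree_contraction", "num_components", "contraction_constant",
]


class InvalidGeometryError(ValueError):
    """Raised for non-unit or non-finite direction vectors."""


def num_components(degrees) -> int:
    return sum(2 * l + 1 for l in degrees)


def degree_slices(degrees):
    """(start, stop) index pairs of each degree block in the packed vector."""
    out, off = [], 0
    for l in degrees:
        out.append((off, off + 2 * l + 1))
        off += 2 * l + 1
    return out


class SphericalTensor:
    """Packed real spherical tensor: degree-major values, m from -l to l."""

    __slots__ = ("values", "degrees")

    def __init__(self, values, degrees):
        self.values = np.asarray(values, dtype=np.float64)
        self.degrees = tuple(degrees)
        if self.values.shape[-1] != num_components(self.degrees):
            raise ValueError(
                f"expected {num_components(self.degrees)} components for "
                f"degrees {self.degrees}, got {self.values.shape[-1]}"
            )

    def block(self, l):
        for (a, b), ll in zip(degree_slices(self.degrees), self.degrees):
            if ll == l:
                return self.values[..., a:b]
        raise KeyError(f"degree {l} not present")

    def rotate(self, R):
        """Blockwise rotation by the real Wigner-D matrices of ``R``."""
        parts = [self.block(l) @ wigner_d(R, l).T for l in self.degrees]
        return SphericalTensor(np.concatenate(parts, axis=-1), self.degrees)


def real_sph_harm(u, l_max: int) -> SphericalTensor:
    """Real orthonormal spherical harmonics Y_lm(u) for all l <= l_max.

    ``u`` must be a unit 3-vector (checked to 1e-8).
    """
    u = np.asarray(u, dtype=np.float64)
    if u.shape != (3,) or not np.all(np.isfinite(u)):
        raise InvalidGeometryError("direction must be a finite 3-vector")
    if abs(np.linalg.norm(u) - 1.0) > 1e-8:
        raise InvalidGeometryError("direction must be a unit vector")
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    theta = np.arccos(np.clip(u[2], -1.0, 1.0))
    phi = np.arctan2(u[1], u[0])
    vals = []
    for l in range(l_max + 1):
        block = np.empty(2 * l + 1)
        for m in range(-l, l + 1):
            y = sph_harm_y(l, abs(m), theta, phi)
            if m > 0:
                block[l + m] = (-1) ** m * sqrt(2.0) * y.real
            elif m < 0:
                block[l + m] = (-1) ** m * sqrt(2.0) * y.imag
            else:
                block[l] = y.real
        vals.append(block)
    return SphericalTensor(np.concatenate(vals), tuple(range(l_max + 1)))


# -- Wigner rotation matrices in the real basis ----------------------------

def _check_rotation(R):
    R = np.asarray(R, dtype=np.float64)
    if R.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-8:
        raise ValueError("matrix is not orthogonal")
    if np.linalg.det(R) < 0:
        raise ValueError("improper rotation (det = -1) not allowed")
    return R


@lru_cache(maxsize=32)
def _sample_directions(n: int):
    """Deterministic well-spread unit vectors (Fibonacci sphere)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = k * pi * (3.0 - sqrt(5.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def wigner_d(R, l: int):
    """Degree-l rotation matrix D such that Y_l(R u) = D Y_l(u).

    Solved in the least-squares sense from spherical-harmonic values on a
    fixed spread of sample directions; exact up to solver round-off.
    """
    R = _check_rotation(R)
    if l == 0:
        return np.ones((1, 1))
    n = 4 * l + 8
    us = _sample_directions(n)
    a0, a1 = degree_slices(range(l + 1))[l]
    Y = np.stack([real_sph_harm(u, l).values[a0:a1] for u in us])       # n x (2l+1)
    Yr = np.stack([real_sph_harm(R @ u, l).values[a0:a1] for u in us])
    # Y_l(Ru) = D Y_l(u)  ->  Yr = Y D^T
    D, *_ = np.linalg.lstsq(Y, Yr, rcond=None)
    return D.T


# -- Clebsch-Gordan table ---------------------------------------------------

def _cg_complex(l1, m1, l2, m2, L, M) -> float:
    """Condon-Shortley complex-basis Clebsch-Gordan coefficient (Racah)."""
    if m1 + m2 != M or not abs(l1 - l2) <= L <= l1 + l2:
        return 0.0
    if abs(m1) > l1 or abs(m2) > l2 or abs(M) > L:
        return 0.0
    f = factorial
    pref = sqrt(
        (2 * L + 1)
        * f(L + l1 - l2) * f(L - l1 + l2) * f(l1 + l2 - L)
        / f(l1 + l2 + L + 1)
    )
    pref *= sqrt(
        f(L + M) * f(L - M) * f(l1 - m1) * f(l1 + m1) * f(l2 - m2) * f(l2 + m2)
    )
    s = 0.0
    for k in range(0, l1 + l2 - L + 1):
        denom_terms = (
            k, l1 + l2 - L - k, l1 - m1 - k, l2 + m2 - k,
            L - l2 + m1 + k, L - l1 - m2 + k,
        )
        if any(t < 0 for t in denom_terms):
            continue
        d = 1.0
        for t in denom_terms:
            d *= f(t)
        s += (-1.0) ** k / d
    return pref * s


@lru_cache(maxsize=8)
def _real_basis_matrix(l: int):
    """Unitary U with realY_m = sum_mu U[m, mu] complexY_mu (mu = -l..l)."""
    U = np.zeros((2 * l + 1, 2 * l + 1), dtype=np.complex128)
    U[l, l] = 1.0
    for m in range(1, l + 1):
        U[l + m, l + m] = (-1) ** m / sqrt(2.0)
        U[l + m, l - m] = 1.0 / sqrt(2.0)
        U[l - m, l + m] = -1j * (-1) ** m / sqrt(2.0)
        U[l - m, l - m] = 1j / sqrt(2.0)
    return U


class CGTable:
    """Real-basis Clebsch-Gordan coefficients up to ``l_max``.

    ``table[(l1, l2, L)]`` is a (2l1+1, 2l2+1, 2L+1) real array indexed by
    (m1, m2, M) offsets.  Blocks violating |l1-l2| <= L <= l1+l2 are zero.
    Used by the brute-force convolution oracle and the tests only.
    """

    def __init__(self, l_max: int):
        if l_max < 0:
            raise ValueError("l_max must be >= 0")
        self.l_max = l_max
        self.blocks = {}
        for l1 in range(l_max + 1):
            for l2 in range(l_max + 1):
                for L in range(l_max + 1):
                    self.blocks[(l1, l2, L)] = self._block(l1, l2, L)

    @staticmethod
    def _block(l1, l2, L):
        if not abs(l1 - l2) <= L <= l1 + l2:
            return np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * L + 1))
        Cc = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * L + 1))
        for i1, mu1 in enumerate(range(-l1, l1 + 1)):
            for i2, mu2 in enumerate(range(-l2, l2 + 1)):
                mu = mu1 + mu2
                if abs(mu) <= L:
                    Cc[i1, i2, L + mu] = _cg_complex(l1, mu1, l2, mu2, L, mu)
        U1 = _real_basis_matrix(l1).conj()
        U2 = _real_basis_matrix(l2).conj()
        UL = _real_basis_matrix(L)
        # real components transform like the harmonics (realY = U complexY),
        # so the coupled real coefficients follow by the unitary basis change
        Z = np.einsum("Mw,au,bv,uvw->abM", UL, U1, U2, Cc)
        # blocks with odd l1+l2+L carry a uniform phase i in this convention;
        # strip it (an overall block phase does not affect equivariance)
        if np.abs(Z.imag).max() > np.abs(Z.real).max():
            return np.ascontiguousarray(Z.imag)
        return np.ascontiguousarray(Z.real)

    def coefficient(self, l1, m1, l2, m2, L, M) -> float:
        block = self.blocks[(l1, l2, L)]
        return float(block[l1 + m1, l2 + m2, L + M])

    def couple(self, x: SphericalTensor, y: SphericalTensor, L: int):
        """Brute-force tensor-product coupling to total degree L (oracle)."""
        out = np.zeros(x.values.shape[:-1] + (2 * L + 1,))
        for l1 in x.degrees:
            for l2 in y.degrees:
                C = self.blocks.get((l1, l2, L))
                if C is None or not C.any():
                    continue
                out += np.einsum("...a,...b,abM->...M", x.block(l1), y.block(l2), C)
        return out


@lru_cache(maxsize=8)
def cg_table(l_max: int) -> CGTable:
    """Build (once per l_max, cached) the real-basis CG table."""
    return CGTable(l_max)


# -- per-degree invariant contraction ---------------------------------------

def contraction_constant(l: int) -> float:
    """The pinned per-degree constant: invariant_l = sum_m x_lm^2 * c_l."""
    return 1.0 / sqrt(2 * l + 1)


def degree_contraction(x: SphericalTensor):
    """One rotation invariant per degree: sum_m x_lm^2 / sqrt(2l+1).

    This equals (up to the fixed per-degree constant) the projection of the
    tensor product x (x) x onto total degree L = 0, computed here with a
    per-degree sum instead of a full Clebsch-Gordan contraction.
    """
    return np.stack(
        [ (x.block(l) ** 2).sum(axis=-1) * contraction_constant(l)
          for l in x.degrees ],
        axis=-1,
    )
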