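"""Trajectory observables: RDF, power spectra, geometry, normal modes."""

import numpy as np
import pytest

from euclidff.data import ACCEL_CONV, C_LIGHT_CM_FS, HBAR, KB
from euclidff.dynamics import MDConfig, MDState, Trajectory, init_velocities, run_md
from euclidff.graph import AtomicSystem
from euclidff.observables import (dihedral, end_to_end_distance, normal_modes,
                                  radius_of_gyration, rdf, vacf_spectrum,
                                  zpe_temperature)
from euclidff.synthdata import HarmonicMolecule


def static_traj(system, n_frames=1, velocities=None, dt=1.0):
    v = velocities if velocities is not None else np.zeros_like(system.positions)
    frames = [MDState(system.positions.copy(), v.copy(), system.masses, float(k))
              for k in range(n_frames)]
    return Trajectory(frames, dt=dt, stride=1, thermostat="static", system=system)


class TestRDF:
    def test_ideal_gas_is_flat(self, rng):
        cell = np.eye(3) * 12.0
        frames = []
        s0 = AtomicSystem([18] * 60, rng.uniform(0, 12, size=(60, 3)),
                          cell=cell, pbc=True)
        traj_frames = []
        for _ in range(40):
            pos = rng.uniform(0, 12, size=(60, 3))
            traj_frames.append(MDState(pos, np.zeros((60, 3)), s0.masses))
        traj = Trajectory(traj_frames, dt=1.0, stride=1, thermostat="x", system=s0)
        r, g = rdf(traj, r_max=5.0, n_bins=25)
        assert np.abs(g[5:] - 1.0).mean() < 0.1  # sampling noise only

    def test_rigid_dimer_single_bin_peak(self):
        s = AtomicSystem([18, 18], [[0, 0, 0], [3.0, 0, 0]])
        traj = static_traj(s, n_frames=3)
        r, g = rdf(traj, r_max=5.0, n_bins=50)
        assert np.count_nonzero(g) == 1
        assert abs(r[np.argmax(g)] - 3.0) <= 0.05  # within one bin

    def test_fcc_like_shell_coordination_count(self):
        """Integrating rho g(r) 4 pi r^2 dr over the first peak recovers the
        direct neighbor count of a simple-cubic lattice fixture."""
        a = 3.0
        n_side = 4
        pts = np.array([[i, j, k] for i in range(n_side)
                        for j in range(n_side) for k in range(n_side)]) * a
        cell = np.eye(3) * (n_side * a)
        s = AtomicSystem([18] * len(pts), pts, cell=cell, pbc=True)
        traj = static_traj(s)
        r, g = rdf(traj, r_max=5.0, n_bins=100)
        rho = len(pts) / np.linalg.det(cell)
        dr = r[1] - r[0]
        mask = (r > a - 0.3) & (r < a + 0.3)
        coord = np.sum(rho * g[mask] * 4 * np.pi * r[mask] ** 2 * dr)
        assert coord == pytest.approx(6.0, rel=0.05)  # simple cubic: 6 neighbors

    def test_empty_selection_rejected(self):
        s = AtomicSystem([18, 18], [[0, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError):
            rdf(static_traj(s), pair_selection=([], [0]))


class TestVACFSpectrum:
    def test_analytic_oscillation_peaks_at_omega(self):
        """Synthetic cosine velocities: the peak lands within one FFT bin of
        omega/(2 pi c)."""
        omega = 0.05  # 1/fs
        t = np.arange(4096) * 0.5
        s = AtomicSystem([6, 6], [[0, 0, 0], [1.5, 0, 0]])
        frames = []
        for k, tk in enumerate(t):
            v = np.zeros((2, 3))
            v[0, 0] = np.cos(omega * tk)
            v[1, 0] = -np.cos(omega * tk)
            frames.append(MDState(s.positions.copy(), v, s.masses, tk))
        traj = Trajectory(frames, dt=0.5, stride=1, thermostat="x", system=s)
        spec = vacf_spectrum(traj)
        expect = omega / (2 * np.pi) / C_LIGHT_CM_FS
        assert abs(spec.peak_wavenumber() - expect) <= spec.bin_width

    def test_zero_velocities_zero_spectrum(self):
        s = AtomicSystem([6, 6], [[0, 0, 0], [1.5, 0, 0]])
        spec = vacf_spectrum(static_traj(s, n_frames=64))
        assert np.allclose(spec.intensity, 0)

    def test_two_uncoupled_oscillators_two_peaks(self):
        om1, om2 = 0.03, 0.09
        t = np.arange(8192) * 0.5
        s = AtomicSystem([6] * 4, np.diag([1.0, 2.0, 3.0, 4.0])[:, :3] * 3)
        frames = []
        for tk in t:
            v = np.zeros((4, 3))
            v[0, 0] = np.cos(om1 * tk)
            v[1, 0] = -np.cos(om1 * tk)
            v[2, 1] = np.cos(om2 * tk)
            v[3, 1] = -np.cos(om2 * tk)
            frames.append(MDState(s.positions.copy(), v, s.masses, tk))
        traj = Trajectory(frames, dt=0.5, stride=1, thermostat="x", system=s)
        spec = vacf_spectrum(traj)
        for om in (om1, om2):
            wn = om / (2 * np.pi) / C_LIGHT_CM_FS
            k = np.argmin(np.abs(spec.wavenumbers - wn))
            window = spec.intensity[max(k - 2, 0):k + 3]
            assert window.max() > 0.2 * spec.intensity.max()

    def test_too_few_frames_rejected(self):
        s = AtomicSystem([6, 6], [[0, 0, 0], [1.5, 0, 0]])
        with pytest.raises(ValueError):
            vacf_spectrum(static_traj(s, n_frames=1))


class TestGeometry:
    def test_rog_coincident_atoms(self):
        assert radius_of_gyration(np.zeros((4, 3)), np.ones(4)) == 0.0

    def test_rog_two_equal_masses(self):
        pos = np.array([[0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pos, np.ones(2)) == pytest.approx(1.0)

    def test_rog_rigid_motion_invariant(self, rng):
        from conftest import random_rotation
        pos = rng.normal(size=(6, 3))
        m = rng.uniform(1, 12, size=6)
        R = random_rotation(rng)
        assert radius_of_gyration(pos @ R.T + 5.0, m) == \
            pytest.approx(radius_of_gyration(pos, m))

    def test_end_to_end(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [2.0, 0, 0]])
        assert end_to_end_distance(pos, 0, 2) == pytest.approx(2.0)
        assert end_to_end_distance(pos, 1, 1) == 0.0
        with pytest.raises(IndexError):
            end_to_end_distance(pos, 0, 5)

    def test_dihedral_cis_trans_and_chirality(self):
        cis = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        assert dihedral(cis, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-10)
        trans = cis.copy()
        trans[3] = [1, -1, 0]
        assert abs(dihedral(trans, 0, 1, 2, 3)) == pytest.approx(180.0)
        skew = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0.5, 0.8]])
        mirrored = skew * np.array([1, 1, -1.0])
        assert dihedral(mirrored, 0, 1, 2, 3) == pytest.approx(
            -dihedral(skew, 0, 1, 2, 3))
        collinear = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(ValueError):
            dihedral(collinear, 0, 1, 2, 3)


class TestNormalModes:
    def test_diatomic_frequency_closed_form(self):
        k, r0 = 5.0, 1.5
        pot = HarmonicMolecule(bonds=((0, 1),), k=k, r0=r0)
        s = AtomicSystem([6, 6], [[0, 0, 0], [r0, 0, 0]])
        res = normal_modes(s, pot)
        mu = s.masses[0] / 2
        omega = np.sqrt(k * ACCEL_CONV / mu)
        expect = omega / (2 * np.pi * C_LIGHT_CM_FS)
        assert len(res.frequencies) == 1
        assert res.frequencies[0] == pytest.approx(expect, rel=1e-4)
        assert res.zpe == pytest.approx(0.5 * HBAR * omega, rel=1e-4)

    def test_nonlinear_triatomic_has_three_modes(self, triangle_molecule):
        pot, s = triangle_molecule
        res = normal_modes(s, pot)
        assert len(res.frequencies) == 3
        assert res.is_minimum

    def test_zpe_of_independent_springs_is_additive(self):
        """Two decoupled diatomics: ZPE = 1/2 hbar (omega1 + omega2)."""
        k1, k2 = 4.0, 9.0
        pot = HarmonicMolecule(bonds=((0, 1), (2, 3), (1, 2)),
                               k=np.array([k1, k2, 1e-8]),
                               r0=np.array([1.5, 1.5, 20.0]))
        pos = np.array([[0, 0, 0], [1.5, 0, 0], [21.5, 0, 0], [23.0, 0, 0.0]])
        s = AtomicSystem([6, 6, 6, 6], pos)
        res = normal_modes(s, pot)
        mu = s.masses[0] / 2
        zpe_expect = 0.5 * HBAR * (
            np.sqrt(k1 * ACCEL_CONV / mu) + np.sqrt(k2 * ACCEL_CONV / mu))
        assert res.zpe == pytest.approx(zpe_expect, rel=1e-3)

    def test_non_minimum_reports_imaginary_modes(self):
        from euclidff.synthdata import DoubleWellMolecule
        dw = DoubleWellMolecule(r_a=1.2, r_b=2.0, barrier=0.5)
        s = AtomicSystem([6, 6], [[0, 0, 0], [1.6, 0, 0]])  # barrier top
        res = normal_modes(s, dw)
        assert not res.is_minimum
        assert len(res.imaginary_frequencies) == 1


class TestZPETemperature:
    def test_worked_example_rounds_to_930K(self):
        assert round(zpe_temperature(12.979, 56), -1) == 930.0

    def test_zero_energy(self):
        assert zpe_temperature(0.0, 10) == 0.0

    def test_linear_in_energy(self):
        assert zpe_temperature(2.0, 10) == pytest.approx(2 * zpe_temperature(1.0, 10))

    def test_small_molecules_rejected(self):
        with pytest.raises(ValueError):
            zpe_temperature(1.0, 2)


def test_spectrum_peaks_match_normal_modes(triangle_molecule):
    """Internal consistency: MD power spectrum of the harmonic molecule
    peaks at the harmonic-analysis frequencies (one-bin agreement)."""
    pot, s = triangle_molecule
    res = normal_modes(s, pot)
    v0 = init_velocities(s, 40.0, mode="rescale_exact", seed=3,
                         remove_rotation=True)
    traj = run_md(s, pot, MDConfig(dt=0.5, steps=16384, stride=2), velocities=v0)
    spec = vacf_spectrum(traj)
    background = np.median(spec.intensity)
    for wn in res.frequencies:
        # the local maximum near each mode lies within one bin of it and
        # stands far above the background
        k = np.argmin(np.abs(spec.wavenumbers - wn))
        window = slice(max(k - 6, 0), k + 7)
        k_peak = np.argmax(spec.intensity[window]) + window.start
        assert abs(spec.wavenumbers[k_peak] - wn) <= spec.bin_width
        assert spec.intensity[k_peak] > 50 * background


def test_rog_distribution_converges_on_langevin_chain():
    """First vs second half of a long thermostatted run of a toy chain:
    Kolmogorov-Smirnov distance below 0.05 (stationarity at toy scale).

    The chain is braced with next-neighbor and end-to-end springs so every
    deformation has a restoring force: the ROG then decorrelates within a
    few sampling intervals and the two halves are genuinely comparable."""
    from scipy.stats import ks_2samp

    bonds = ((0, 1), (1, 2), (2, 3), (0, 2), (1, 3), (0, 3))
    k = np.array([5.0, 5.0, 5.0, 2.0, 2.0, 1.0])
    r0 = np.array([1.5, 1.5, 1.5, 2.7, 2.7, 3.6])
    pot = HarmonicMolecule(bonds=bonds, k=k, r0=r0)
    pos = np.zeros((4, 3))
    pos[:, 0] = np.arange(4) * 1.5
    pos[1, 1] = pos[2, 1] = 0.3
    s = AtomicSystem([6] * 4, pos)
    cfg = MDConfig(dt=2.0, steps=120_000, stride=40, integrator="langevin",
                   temperature=300.0, gamma=0.05, seed=7)
    traj = run_md(s, pot, cfg)
    rogs = np.array([radius_of_gyration(f.positions, s.masses)
                     for f in traj.frames])
    burn = len(rogs) // 10
    rogs = rogs[burn:]
    half = len(rogs) // 2
    stat = ks_2samp(rogs[:half], rogs[half:]).statistic
    assert stat < 0.05
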