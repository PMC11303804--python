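"""The Euclidean transformer: components, symmetries, gradients."""

import numpy as np
import pytest

from euclidff import so3
from euclidff.engine import Tensor
from euclidff.graph import AtomicSystem, build_neighbors
from euclidff.network import (EuclideanState, FeatureState, ModelConfig,
                              NetworkPotential, attention_block,
                              attention_coeffs, count_params, cutoff, embed,
                              energy_and_forces, filter_w, forces,
                              forward_energy, init_ev, init_params,
                              interaction_block, rbf)

from conftest import random_rotation


def rotate_ev(values, degrees, R):
    return np.stack([
        so3.SphericalTensor(v, degrees).rotate(R).values for v in values
    ])


class TestConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(feature_dim=30, heads=4)
        with pytest.raises(ValueError):
            ModelConfig(feature_dim=32, heads=4, degrees=(0, 1, 2))

    def test_rbf_centers_span_exp_interval(self):
        cfg = ModelConfig(r_cut=5.0, n_rbf=8)
        assert cfg.rbf_centers[0] == pytest.approx(np.exp(-5.0))
        assert cfg.rbf_centers[-1] == pytest.approx(1.0)


class TestEmbedding:
    def test_equal_elements_equal_rows(self, small_model):
        cfg, params, _ = small_model
        f = embed(np.array([6, 1, 6]), params, cfg)
        assert np.array_equal(f.values[0], f.values[2])
        assert not np.array_equal(f.values[0], f.values[1])

    def test_permutation_permutes_rows(self, small_model):
        cfg, params, _ = small_model
        z = np.array([1, 6, 8])
        perm = [2, 0, 1]
        assert np.array_equal(
            embed(z[perm], params, cfg).values, embed(z, params, cfg).values[perm]
        )

    def test_out_of_table_element_is_named(self, small_model):
        cfg, params, _ = small_model
        with pytest.raises(ValueError, match="119"):
            embed(np.array([119]), params, cfg)


class TestEVInitialization:
    def test_isolated_atom_gives_zero_ev(self, small_model):
        cfg, params, _ = small_model
        s = AtomicSystem([6], [[0, 0, 0]])
        ev = init_ev(s, build_neighbors(s, cfg.r_cut), cfg)
        assert np.all(ev.values == 0)

    def test_single_neighbor_along_z_degree0(self, small_model):
        cfg, _, _ = small_model
        r = 2.0
        s = AtomicSystem([6, 6], [[0, 0, 0], [0, 0, r]])
        ev = init_ev(s, build_neighbors(s, cfg.r_cut), cfg)
        expected = cutoff(r, cfg.r_cut) / (2 * np.sqrt(np.pi)) / cfg.mean_neighbors
        assert ev.values[0, 0] == pytest.approx(expected)

    def test_centrosymmetric_shell_kills_odd_degrees(self, small_model):
        cfg, _, _ = small_model
        pos = [[0, 0, 0], [2, 0, 0], [-2, 0, 0], [0, 2, 0], [0, -2, 0],
               [0, 0, 2], [0, 0, -2]]
        s = AtomicSystem([6] * 7, pos)
        ev = init_ev(s, build_neighbors(s, cfg.r_cut), cfg)
        x = so3.SphericalTensor(ev.values[0], cfg.degrees)
        assert np.allclose(x.block(1), 0, atol=1e-14)
        assert np.allclose(x.block(3), 0, atol=1e-14)
        assert not np.allclose(x.block(0), 0)

    def test_zeros_mode(self, small_model):
        cfg, _, _ = small_model
        cfg2 = ModelConfig(**{**cfg.to_dict(), "ev_init": "zeros"})
        s = AtomicSystem([6, 6], [[0, 0, 0], [0, 0, 2]])
        assert np.all(init_ev(s, build_neighbors(s, cfg2.r_cut), cfg2).values == 0)


def test_cutoff_function_values():
    assert cutoff(0.0, 5.0) == pytest.approx(1.0)
    assert cutoff(5.0, 5.0) == pytest.approx(0.0)
    assert cutoff(2.5, 5.0) == pytest.approx(0.5)
    assert cutoff(7.0, 5.0) == 0.0


def test_rbf_unit_peak_and_range():
    cfg = ModelConfig(r_cut=5.0, n_rbf=8)
    r_at_center = -np.log(cfg.rbf_centers[3])
    g = rbf(r_at_center, cfg)
    assert g[3] == pytest.approx(1.0)
    r = np.linspace(0, 5, 50)
    G = rbf(r, cfg)
    assert np.all((G > 0) & (G <= 1))


class TestFilter:
    def test_zero_weights_give_zero_filter(self, small_model):
        cfg, params, _ = small_model
        zeroed = {k: Tensor(np.zeros_like(p.data)) for k, p in params.items()}
        w = filter_w(np.ones(cfg.n_rbf), np.ones(cfg.n_degrees), zeroed, cfg)
        assert np.all(w == 0)

    def test_branches_are_additive(self, small_model, rng):
        cfg, params, _ = small_model
        g = rng.uniform(size=cfg.n_rbf)
        u = rng.uniform(size=cfg.n_degrees)
        w_full = filter_w(g, u, params, cfg)
        w_g = filter_w(g, np.zeros(cfg.n_degrees), params, cfg)
        w_u = filter_w(np.zeros(cfg.n_rbf), u, params, cfg)
        w_0 = filter_w(np.zeros(cfg.n_rbf), np.zeros(cfg.n_degrees), params, cfg)
        assert np.allclose(w_full, w_g + w_u - w_0, atol=1e-12)


class TestAttentionCoefficients:
    def test_zero_filter_zero_coefficients(self, small_model, rng):
        cfg, params, _ = small_model
        f = rng.normal(size=cfg.feature_dim)
        a, al = attention_coeffs(f, f, np.zeros(cfg.feature_dim), params, cfg)
        assert np.all(a == 0) and np.all(al == 0)

    def test_identity_projections_single_head(self):
        cfg = ModelConfig(feature_dim=8, heads=1, blocks=1, degrees=(0,),
                          n_rbf=4, mean_neighbors=1.0)
        params = init_params(cfg, 0)
        I = Tensor(np.eye(8))
        params["block0/Qf"] = I
        params["block0/Kf"] = I
        e1 = np.zeros(8)
        e1[0] = 1.0
        a, _ = attention_coeffs(e1, e1, np.ones(8), params, cfg)
        assert a[0, 0] == pytest.approx(1 / np.sqrt(8))

    def test_rotation_leaves_coefficients_unchanged(self, small_model, rng):
        """Coefficients depend on invariant inputs only: rebuilding the edge
        filter from a rotated geometry changes nothing."""
        cfg, params, system = small_model
        R = random_rotation(rng)
        nl = build_neighbors(system, cfg.r_cut)
        nl_rot = build_neighbors(system.with_positions(system.positions @ R.T), cfg.r_cut)
        ev = init_ev(system, nl, cfg)
        ev_r = init_ev(system.with_positions(system.positions @ R.T), nl_rot, cfg)
        f = embed(system.atomic_numbers, params, cfg)
        for e in range(nl.n_edges):
            i, j = nl.idx_i[e], nl.idx_j[e]
            u = so3.degree_contraction(
                so3.SphericalTensor(ev.values[j] - ev.values[i], cfg.degrees))
            u_r = so3.degree_contraction(
                so3.SphericalTensor(ev_r.values[j] - ev_r.values[i], cfg.degrees))
            g = rbf(nl.distances[e], cfg)
            w = filter_w(g, u, params, cfg)
            w_r = filter_w(g, u_r, params, cfg)
            a, al = attention_coeffs(f.values[i], f.values[j], w, params, cfg)
            a_r, al_r = attention_coeffs(f.values[i], f.values[j], w_r, params, cfg)
            assert np.allclose(a, a_r, atol=1e-12)
            assert np.allclose(al, al_r, atol=1e-12)


class TestBlocks:
    def test_isolated_atom_unchanged_by_attention(self, small_model, rng):
        cfg, params, _ = small_model
        s = AtomicSystem([6], [[0, 0, 0]])
        nl = build_neighbors(s, cfg.r_cut)
        f = FeatureState(rng.normal(size=(1, cfg.feature_dim)))
        ev = EuclideanState(rng.normal(size=(1, cfg.ev_dim)), cfg.degrees)
        f2, ev2 = attention_block(f, ev, s, nl, params, cfg)
        assert np.allclose(f2.values, f.values)
        assert np.allclose(ev2.values, ev.values)

    def test_attention_block_is_equivariant(self, small_model, rng):
        cfg, params, system = small_model
        R = random_rotation(rng)
        nl = build_neighbors(system, cfg.r_cut)
        sys_r = system.with_positions(system.positions @ R.T)
        nl_r = build_neighbors(sys_r, cfg.r_cut)
        f = embed(system.atomic_numbers, params, cfg)
        ev = init_ev(system, nl, cfg)
        ev_r = init_ev(sys_r, nl_r, cfg)
        assert np.allclose(ev_r.values, rotate_ev(ev.values, cfg.degrees, R), atol=1e-10)
        f2, x2 = attention_block(f, ev, system, nl, params, cfg)
        f2r, x2r = attention_block(f, ev_r, sys_r, nl_r, params, cfg)
        assert np.allclose(f2r.values, f2.values, atol=1e-10)       # invariant
        assert np.allclose(x2r.values, rotate_ev(x2.values, cfg.degrees, R), atol=1e-10)

    def test_zero_interaction_weights_identity_update(self, small_model, rng):
        cfg, params, _ = small_model
        zeroed = dict(params)
        for t in range(cfg.blocks):
            zeroed[f"block{t}/Wi"] = Tensor(np.zeros_like(params[f"block{t}/Wi"].data))
            zeroed[f"block{t}/bi"] = Tensor(np.zeros_like(params[f"block{t}/bi"].data))
        f = FeatureState(rng.normal(size=(3, cfg.feature_dim)))
        ev = EuclideanState(rng.normal(size=(3, cfg.ev_dim)), cfg.degrees)
        f2, ev2 = interaction_block(f, ev, zeroed, cfg)
        assert np.allclose(f2.values, f.values)
        assert np.allclose(ev2.values, ev.values)

    def test_interaction_refinement_linear_in_ev(self, small_model, rng):
        """With the gains frozen (same invariants), dx doubles with x."""
        cfg, params, _ = small_model
        f = FeatureState(rng.normal(size=(2, cfg.feature_dim)))
        ev = EuclideanState(rng.normal(size=(2, cfg.ev_dim)), cfg.degrees)
        _, ev1 = interaction_block(f, ev, params, cfg)
        dx = ev1.values - ev.values
        # recompute the gains at the original invariants, apply to doubled EV
        from euclidff.network import _contract_t, _degree_expand_index
        import euclidff.engine as eg
        ui = _contract_t(Tensor(ev.values), cfg.degrees)
        y = eg.concat([Tensor(f.values), ui], axis=1)
        ab = eg.silu(eg.matmul(y, params["block0/Wi"]) + params["block0/bi"])
        bl = ab.data[:, cfg.feature_dim:]
        gains = bl[:, _degree_expand_index(cfg.degrees)]
        assert np.allclose(dx, gains * ev.values, atol=1e-12)
        assert np.allclose(2 * dx, gains * (2 * ev.values), atol=1e-12)


class TestFullModel:
    def test_energy_invariances_and_force_equivariance(self, small_model, rng):
        cfg, params, system = small_model
        E0, F0 = energy_and_forces(system, params, cfg)
        R = random_rotation(rng)
        E1, F1 = energy_and_forces(
            system.with_positions(system.positions @ R.T + 2.0), params, cfg)
        assert E1 == pytest.approx(E0, rel=1e-12)
        assert np.allclose(F1, F0 @ R.T, atol=1e-10)
        perm = rng.permutation(system.n_atoms)
        E2, _ = energy_and_forces(
            AtomicSystem(system.atomic_numbers[perm], system.positions[perm]),
            params, cfg)
        assert E2 == pytest.approx(E0, rel=1e-12)
        E3, _ = energy_and_forces(system.with_positions(-system.positions), params, cfg)
        assert E3 == pytest.approx(E0, rel=1e-12)  # parity-even contractions

    def test_forces_sum_to_zero(self, small_model):
        cfg, params, system = small_model
        F = forces(system, params, cfg)
        assert np.allclose(F.sum(axis=0), 0, atol=1e-10)

    def test_forces_match_finite_differences(self, small_model):
        cfg, params, system = small_model
        E0, F = energy_and_forces(system, params, cfg)
        h = 1e-4
        scale = np.abs(F).max()
        for (i, k) in [(0, 0), (2, 1), (5, 2)]:
            pp, pm = system.positions.copy(), system.positions.copy()
            pp[i, k] += h
            pm[i, k] -= h
            ep, _ = forward_energy(system.with_positions(pp), params, cfg)
            em, _ = forward_energy(system.with_positions(pm), params, cfg)
            assert -(ep - em) / (2 * h) == pytest.approx(F[i, k], abs=1e-5 * scale)

    def test_isolated_atoms_are_additive(self, small_model):
        cfg, params, _ = small_model
        e1, _ = forward_energy(AtomicSystem([6], [[0, 0, 0]]), params, cfg)
        e2, _ = forward_energy(
            AtomicSystem([6, 6], [[0, 0, 0], [40, 0, 0]]), params, cfg)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_energy_continuous_across_cutoff(self, small_model):
        cfg, params, _ = small_model
        eps = 1e-9
        e_in, _ = forward_energy(
            AtomicSystem([6, 6], [[0, 0, 0], [cfg.r_cut - eps, 0, 0]]), params, cfg)
        e_out, _ = forward_energy(
            AtomicSystem([6, 6], [[0, 0, 0], [cfg.r_cut + eps, 0, 0]]), params, cfg)
        assert e_in == pytest.approx(e_out, abs=1e-8)

    def test_ev_memory_is_sum_of_block_sizes(self, small_model):
        cfg, _, system = small_model
        nl = build_neighbors(system, cfg.r_cut)
        ev = init_ev(system, nl, cfg)
        assert ev.values.shape == (system.n_atoms,
                                   sum(2 * l + 1 for l in cfg.degrees))


class TestParameterCount:
    def test_embedding_table_alone(self):
        cfg = ModelConfig(feature_dim=8, heads=1, blocks=1, degrees=(0,),
                          n_rbf=4, max_atomic_number=10)
        params = {"embedding": Tensor(np.zeros((10, 8)))}
        assert count_params(params) == 80

    def test_deterministic_across_builds(self):
        cfg = ModelConfig()
        assert count_params(init_params(cfg, 3)) == count_params(init_params(cfg, 4))

    def test_invariant_vs_equivariant_models_differ_little(self):
        """Raising l_max changes the parameter count by well under 25%:
        geometric information, not capacity, separates the variants."""
        base = dict(feature_dim=132, heads=4, blocks=3, n_rbf=32)
        n_inv = count_params(init_params(ModelConfig(degrees=(0,), **base), 0))
        n_eqv = count_params(init_params(ModelConfig(degrees=(0, 1, 2, 3), **base), 0))
        assert abs(n_inv - n_eqv) / max(n_inv, n_eqv) < 0.25


def test_network_potential_protocol(small_model):
    cfg, params, system = small_model
    pot = NetworkPotential(params, cfg)
    e, f = pot.energy_and_forces(system)
    assert np.isfinite(e) and f.shape == (system.n_atoms, 3)
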