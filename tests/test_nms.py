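import numpy as np
import pytest

from molforge import constants, nms
from molforge.calculator import (QuadraticCalculator, Structure3D,
                                 ToyForceField, atomic_mass)
from molforge.chemgraph import ChemicalGraph
from molforge.conformer import Conformer, embed_initial, local_optimize
from molforge.fixtures import toy_diatomic, toy_linear_triatomic


@pytest.fixture(scope="module")
def water_nms(water_minimum):
    g, ff, conf = water_minimum
    hess, energies = nms.finite_difference_hessian(conf.structure, ff)
    return g, ff, conf, hess, energies


class TestFiniteDifferenceHessian:
    def test_diatomic_matches_analytic(self):
        ff, s = toy_diatomic(k=30.0)
        hess, _ = nms.finite_difference_hessian(s, ff)
        ha = ff.analytic_hessian(s.positions)
        scale = np.abs(ha).max()
        assert np.abs(hess - ha).max() / scale < 1e-8

    def test_water_matches_analytic(self, water_nms):
        _, ff, conf, hess, _ = water_nms
        ha = ff.analytic_hessian(conf.positions)
        assert np.abs(hess - ha).max() < 1e-6

    def test_symmetrization_residual_small(self, water_minimum):
        g, ff, conf = water_minimum
        # recompute the raw asymmetry by stenciling twice
        hess, _ = nms.finite_difference_hessian(conf.structure, ff)
        assert np.abs(hess - hess.T).max() < 1e-12  # symmetrized exactly

    def test_translation_nullspace(self, water_nms):
        _, _, conf, hess, _ = water_nms
        n = conf.structure.n_atoms
        trans = np.tile(np.eye(3), (n, 1))
        assert np.abs(hess @ trans).max() < 1e-6

    def test_stencil_energy_count(self, water_nms):
        _, _, conf, _, energies = water_nms
        assert energies.shape == (3 * conf.structure.n_atoms, 6)


class TestSaddleCheck:
    def test_minimum_passes(self, water_nms):
        _, ff, conf, _, energies = water_nms
        e0 = ff.evaluate(conf.structure).energy
        assert nms.saddle_point_check(energies, e0) is True

    def test_1d_saddle_fails(self):
        # E(x) = -x^2 + x^4 at x=0: energy decreases for small displacement
        h = constants.HESSIAN_STEP_A
        offsets = np.array([-3, -2, -1, 1, 2, 3]) * h
        energies = (-offsets ** 2 + offsets ** 4).reshape(1, 6)
        assert nms.saddle_point_check(energies, 0.0) is False

    def test_flat_direction_fails(self):
        energies = np.zeros((1, 6))
        assert nms.saddle_point_check(energies, 0.0) is False


class TestNormalModeAnalysis:
    def test_water_nf_3(self, water_nms):
        _, _, conf, hess, _ = water_nms
        result = nms.normal_mode_analysis(hess, conf.structure.masses,
                                          conf.structure)
        assert result.n_f == 3
        assert result.linear is False

    def test_linear_triatomic_nf_4(self):
        calc, s = toy_linear_triatomic()
        hess, _ = nms.finite_difference_hessian(s, calc)
        result = nms.normal_mode_analysis(hess, s.masses, s)
        assert result.n_f == 4
        assert result.linear is True
        assert np.allclose(sorted(result.force_constants),
                           [5.0, 8.0, 20.0, 30.0], atol=1e-6)

    def test_diatomic_closed_form(self):
        ff, s = toy_diatomic(k=30.0)
        hess = ff.analytic_hessian(s.positions)
        result = nms.normal_mode_analysis(hess, s.masses, s)
        mu = atomic_mass(1) / 2.0
        assert result.n_f == 1
        assert result.force_constants[0] == pytest.approx(30.0 / mu)

    def test_modes_orthonormal(self, water_nms):
        _, _, conf, hess, _ = water_nms
        result = nms.normal_mode_analysis(hess, conf.structure.masses,
                                          conf.structure)
        gram = result.modes @ result.modes.T
        assert np.abs(gram - np.eye(result.n_f)).max() < 1e-8

    def test_saddle_rejected(self, water_nms):
        _, _, conf, hess, _ = water_nms
        with pytest.raises(nms.NotAMinimumError):
            nms.normal_mode_analysis(-hess, conf.structure.masses,
                                     conf.structure)


class TestEnergyDraw:
    def test_zero_temperature(self, rng):
        class ZeroRng:
            def uniform(self, lo, hi):
                return 0.0
        t, e = nms.draw_sample_energy(5, ZeroRng())
        assert (t, e) == (0.0, 0.0)

    def test_constants_arithmetic(self):
        class MaxRng:
            def uniform(self, lo, hi):
                return hi
        t, e = nms.draw_sample_energy(12, MaxRng(), t_max=1000.0)
        assert e == pytest.approx(6.0 * constants.KB_EV * 1000.0)
        assert e == pytest.approx(0.517, abs=2e-3)

    def test_mean_over_many_draws(self, rng):
        n_f, n_draws, t_max = 7, 100_000, 1000.0
        energies = np.array([nms.draw_sample_energy(n_f, rng, t_max)[1]
                             for _ in range(n_draws)])
        expect = 0.5 * n_f * constants.KB_EV * (t_max / 2.0)
        assert energies.mean() == pytest.approx(expect, rel=0.01)


class TestPartitionEnergy:
    def test_zero_energy(self, rng):
        w, e_vec = nms.partition_energy(0.0, 4, rng)
        assert np.all(e_vec == 0.0)

    def test_single_mode_gets_all(self, rng):
        _, e_vec = nms.partition_energy(0.7, 1, rng)
        assert e_vec[0] == 0.7

    def test_exact_sum_many_draws(self, rng):
        import math
        for _ in range(2000):
            e = float(rng.uniform(0, 1.0))
            _, e_vec = nms.partition_energy(e, 9, rng)
            assert math.fsum(e_vec) == e  # exact by construction
            assert np.all(e_vec >= 0.0)

    def test_mean_share_is_uniform(self, rng):
        n_f, n_draws = 5, 100_000
        shares = np.empty((n_draws, n_f))
        for i in range(n_draws):
            _, e_vec = nms.partition_energy(1.0, n_f, rng)
            shares[i] = e_vec
        assert np.allclose(shares.mean(axis=0), 1.0 / n_f, rtol=0.02)


class TestModeDisplacements:
    def test_unit_displacement(self):
        delta = nms.mode_displacements(np.array([0.5 * 3.0]),
                                       np.array([3.0]), np.array([1.0]))
        assert delta[0] == pytest.approx(1.0)

    def test_zero_energy_zero_displacement(self):
        delta = nms.mode_displacements(np.array([0.0]), np.array([2.0]),
                                       np.array([-1.0]))
        assert delta[0] == 0.0

    def test_sign_follows_weights(self, rng):
        w = rng.standard_normal(6)
        e_vec = np.abs(rng.standard_normal(6))
        k = np.abs(rng.standard_normal(6)) + 0.1
        delta = nms.mode_displacements(e_vec, k, w)
        assert np.all(np.sign(delta[e_vec > 0]) == np.sign(w[e_vec > 0]))

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            nms.mode_displacements(np.array([1.0]), np.array([0.0]),
                                   np.array([1.0]))


class TestApplyDisplacements:
    def test_zero_delta_identity(self, water_nms):
        _, ff, conf, hess, _ = water_nms
        result = nms.normal_mode_analysis(hess, conf.structure.masses,
                                          conf.structure)
        s, used = nms.apply_displacements(result, np.zeros(result.n_f),
                                          mode="cartesian")
        assert np.array_equal(s.positions, conf.positions)

    def test_diatomic_closed_form_bond_change(self):
        ff, s = toy_diatomic(k=30.0)
        hess = ff.analytic_hessian(s.positions)
        result = nms.normal_mode_analysis(hess, s.masses, s)
        delta = np.array([0.2])
        displaced, _ = nms.apply_displacements(result, delta,
                                               mode="cartesian")
        r_new = np.linalg.norm(displaced.positions[1]
                               - displaced.positions[0])
        r_old = np.linalg.norm(s.positions[1] - s.positions[0])
        mu = atomic_mass(1) / 2.0
        assert abs(r_new - r_old) == pytest.approx(0.2 / np.sqrt(mu))

    def test_zmatrix_pure_torsion_preserves_bonds(self, ethanol_graph,
                                                  ethanol_minimum):
        # construct an exactly pure torsion mode: rotate the hydroxyl H
        # about the C-O axis (to first order this changes only a dihedral)
        from molforge import zmatrix as zm
        s = ethanol_minimum.structure
        mol = ethanol_graph.to_mol(add_hs=True)
        o_idx = next(a.GetIdx() for a in mol.GetAtoms()
                     if a.GetAtomicNum() == 8)
        h_idx = next(n.GetIdx()
                     for n in mol.GetAtomWithIdx(o_idx).GetNeighbors()
                     if n.GetAtomicNum() == 1)
        c_idx = next(n.GetIdx()
                     for n in mol.GetAtomWithIdx(o_idx).GetNeighbors()
                     if n.GetAtomicNum() == 6)
        axis = s.positions[o_idx] - s.positions[c_idx]
        axis /= np.linalg.norm(axis)
        dx = np.zeros_like(s.positions)
        dx[h_idx] = np.cross(axis, s.positions[h_idx] - s.positions[o_idx])
        q = (dx * np.sqrt(s.masses)[:, None]).reshape(-1)
        q /= np.linalg.norm(q)
        mode_set = nms.NormalModeSet(
            equilibrium=s.copy(), masses=s.masses, modes=q[None, :],
            force_constants=np.array([1.0]), n_f=1, linear=False)
        displaced, used = nms.apply_displacements(
            mode_set, np.array([0.5]), mode="zmatrix")
        assert used == "zmatrix"
        adj = zm.connectivity_from_distances(s.atomic_numbers, s.positions)
        tmpl = zm.build_template(s.atomic_numbers, adj)
        z0 = zm.cart_to_internal(s.positions, tmpl)
        z1 = zm.cart_to_internal(displaced.positions, tmpl)
        n = s.n_atoms
        nb, na = n - 1, n - 2
        assert np.abs(z1[:nb] - z0[:nb]).max() < 1e-4  # bond lengths kept
        assert np.abs(z1[nb:nb + na] - z0[nb:nb + na]).max() < 1e-4
        # and at least one dihedral actually moved
        assert np.abs(z1[nb + na:] - z0[nb + na:]).max() > 0.05

    def test_linear_falls_back_to_cartesian(self):
        calc, s = toy_linear_triatomic()
        hess, _ = nms.finite_difference_hessian(s, calc)
        result = nms.normal_mode_analysis(hess, s.masses, s)
        displaced, used = nms.apply_displacements(
            result, 0.05 * np.ones(result.n_f), mode="zmatrix")
        assert used in ("zmatrix", "cartesian")
        assert np.all(np.isfinite(displaced.positions))


class TestSampleOffequilibrium:
    def test_zero_samples(self, water_minimum, rng):
        g, ff, conf = water_minimum
        assert nms.sample_offequilibrium(conf, ff, 0, rng) == []

    def test_harmonic_round_trip(self, ethanol_ff, ethanol_minimum, rng):
        s = ethanol_minimum.structure
        k = ethanol_ff.analytic_hessian(s.positions)
        calc = QuadraticCalculator(s.atomic_numbers,
                                   s.positions.reshape(-1), k)
        conf = Conformer(s, 0.0, 0, 0.0)
        samples = nms.sample_offequilibrium(conf, calc, 300, rng,
                                            mode="cartesian")
        assert len(samples) == 300
        for displaced, draw in samples:
            realized = calc.evaluate(displaced).energy
            assert realized == pytest.approx(draw.E, rel=1e-6, abs=1e-12)

    def test_determinism(self, ethanol_ff, ethanol_minimum):
        s = ethanol_minimum.structure
        k = ethanol_ff.analytic_hessian(s.positions)
        calc = QuadraticCalculator(s.atomic_numbers,
                                   s.positions.reshape(-1), k)
        conf = Conformer(s, 0.0, 0, 0.0)
        a = nms.sample_offequilibrium(conf, calc, 10,
                                      np.random.default_rng(11))
        b = nms.sample_offequilibrium(conf, calc, 10,
                                      np.random.default_rng(11))
        for (sa, da), (sb, db) in zip(a, b):
            assert np.array_equal(sa.positions, sb.positions)
            assert da.T == db.T

    def test_anharmonic_histogram_roughly_uniform(self, rng):
        # Morse-like toy: realized energies approximate Uniform(0, T_max)
        g = ChemicalGraph.from_smiles("O")
        ff = ToyForceField.from_graph(g, morse=True)
        conf = local_optimize(embed_initial(g, seed=1), ff, f_max=1e-7)
        samples = nms.sample_offequilibrium(conf, ff, 400, rng,
                                            mode="cartesian")
        e0 = ff.evaluate(conf.structure).energy
        n_f = 3
        temps = np.array([
            2.0 * (ff.evaluate(s).energy - e0) / (n_f * constants.KB_EV)
            for s, _ in samples])
        # qualitative: spread over (0, 1000 K), mean near 500 K
        assert 300.0 < temps.mean() < 700.0
        assert temps.min() < 150.0 and temps.max() > 800.0

    def test_saddle_rejected(self, rng):
        # quadratic PES with one negative curvature direction
        calc, s = toy_linear_triatomic(force_constants=(-5.0, 8.0, 20.0,
                                                        30.0))
        conf = Conformer(s, 0.0, 0, 0.0)
        with pytest.raises(nms.NotAMinimumError):
            nms.sample_offequilibrium(conf, calc, 5, rng)


class TestSampleSchedule:
    def test_ramp_endpoints(self):
        assert nms.sample_count_schedule(1) == 100
        assert nms.sample_count_schedule(8) == 1000
        assert nms.sample_count_schedule(12) == 1000  # clamped

    def test_monotone(self):
        counts = [nms.sample_count_schedule(n) for n in range(1, 9)]
        assert counts == sorted(counts)
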