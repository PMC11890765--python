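import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molforge import conformer as cf
from molforge.calculator import Structure3D, ToyForceField, covalent_radius
from molforge.chemgraph import ChemicalGraph
from molforge.fixtures import toy_diatomic


class TestEmbedInitial:
    def test_methane_geometry(self):
        g = ChemicalGraph.from_smiles("C")
        s = cf.embed_initial(g, seed=1)
        assert s.n_atoms == 5
        ref = covalent_radius(6) + covalent_radius(1)
        for k in range(1, 5):
            d = np.linalg.norm(s.positions[k] - s.positions[0])
            assert abs(d - ref) / ref < 0.3

    def test_water_nonlinear(self):
        g = ChemicalGraph.from_smiles("O")
        s = cf.embed_initial(g, seed=1)
        v1 = s.positions[1] - s.positions[0]
        v2 = s.positions[2] - s.positions[0]
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert cosang > -0.999  # not linear

    def test_deterministic_under_seed(self):
        g = ChemicalGraph.from_smiles("CCO")
        a = cf.embed_initial(g, seed=42)
        b = cf.embed_initial(g, seed=42)
        assert np.array_equal(a.positions, b.positions)

    def test_distance_postconditions(self):
        g = ChemicalGraph.from_smiles("CC(C)CO")
        s = cf.embed_initial(g, seed=3)
        assert cf.embed_distance_checks(s, g)


class TestLocalOptimize:
    def test_diatomic_converges_to_r0(self):
        ff, s = toy_diatomic(k=30.0)
        r0 = np.linalg.norm(s.positions[1] - s.positions[0])
        start = Structure3D(s.atomic_numbers,
                            s.positions + [[0, 0, 0], [0.3, 0, 0]])
        conf = cf.local_optimize(start, ff)
        r = np.linalg.norm(conf.positions[1] - conf.positions[0])
        assert abs(r - r0) < 1e-3

    def test_converged_input_returned_quickly(self):
        ff, s = toy_diatomic()
        conf = cf.local_optimize(s, ff)
        assert conf.n_steps <= 1
        assert np.allclose(conf.positions, s.positions)

    def test_fmax_contract(self, ethanol_graph, ethanol_ff):
        s = cf.embed_initial(ethanol_graph, seed=6)
        conf = cf.local_optimize(s, ethanol_ff)
        forces = ethanol_ff.evaluate(conf.structure).forces
        assert np.sqrt((forces ** 2).sum(axis=1)).max() < 5e-3

    def test_reoptimize_is_noop(self, ethanol_graph, ethanol_ff):
        s = cf.embed_initial(ethanol_graph, seed=6)
        conf = cf.local_optimize(s, ethanol_ff)
        again = cf.local_optimize(conf.structure, ethanol_ff)
        assert again.n_steps <= 1
        assert np.allclose(again.positions, conf.positions)

    def test_preopt_rescues_overlapping_start(self, ethanol_graph,
                                              ethanol_ff):
        s = cf.embed_initial(ethanol_graph, seed=6)
        bad = s.positions.copy()
        bad[3] = bad[0] + 0.18  # near-overlapping atom pair
        start = Structure3D(s.atomic_numbers, bad)
        conf = cf.local_optimize(start, ethanol_ff, pre_opt=True,
                                 max_steps=3000)
        forces = ethanol_ff.evaluate(conf.structure).forces
        assert np.sqrt((forces ** 2).sum(axis=1)).max() < 5e-3

    def test_nonconvergence_raises(self):
        ff, s = toy_diatomic(k=30.0)
        start = Structure3D(s.atomic_numbers,
                            s.positions + [[0, 0, 0], [0.5, 0, 0]])
        with pytest.raises(cf.ConvergenceError):
            cf.local_optimize(start, ff, f_max=1e-30, max_steps=3,
                              pre_opt=False)


class TestRotatableBonds:
    def test_ethanol_two(self):
        g = ChemicalGraph.from_smiles("CCO")
        bonds = cf.find_rotatable_bonds(g)
        assert len(bonds) == 2  # C-C and C-O

    def test_cyclopropane_none(self):
        g = ChemicalGraph.from_smiles("C1CC1")
        assert cf.find_rotatable_bonds(g) == []

    def test_cyclohexane_six(self):
        g = ChemicalGraph.from_smiles("C1CCCCC1")
        assert len(cf.find_rotatable_bonds(g)) == 6

    def test_double_bond_excluded(self):
        g = ChemicalGraph.from_smiles("C=C")
        assert cf.find_rotatable_bonds(g) == []

    def test_terminal_halogen_excluded(self):
        g = ChemicalGraph.from_smiles("CF")
        assert cf.find_rotatable_bonds(g) == []

    def test_methanol_oh_included(self):
        g = ChemicalGraph.from_smiles("CO")
        assert len(cf.find_rotatable_bonds(g)) == 1


class TestTorsionDriving:
    def test_set_torsion_reaches_target(self, ethanol_graph):
        # atoms: 0,1 = C, 2 = O, 8 = hydroxyl H (RDKit AddHs ordering)
        s = cf.embed_initial(ethanol_graph, seed=1)
        gx = cf._graph_with_hs(ethanol_graph)
        target = np.radians(73.0)
        pos = cf.set_torsion(s.positions, gx, 0, 1, 2, 8, target)
        got = cf.dihedral_angle(pos[0], pos[1], pos[2], pos[8])
        assert got == pytest.approx(target, abs=1e-10)

    def test_ring_bond_rejected(self):
        g = ChemicalGraph.from_smiles("C1CCCCC1")
        s = cf.embed_initial(g, seed=1)
        gx = cf._graph_with_hs(g)
        with pytest.raises(ValueError):
            cf.set_torsion(s.positions, gx, 2, 0, 1, 3, 1.0)


class TestRMSD:
    def test_kabsch_identity(self, rng):
        p = rng.standard_normal((7, 3))
        rot = Rotation.from_euler("xyz", [0.4, 1.0, -0.7]).as_matrix()
        q = p @ rot.T + np.array([3.0, -1.0, 2.0])
        assert cf.kabsch_rmsd(p, q) < 1e-10

    def test_symmetry_rmsd_leq_naive(self, ethanol_graph, rng):
        s1 = cf.embed_initial(ethanol_graph, seed=1)
        s2 = cf.embed_initial(ethanol_graph, seed=9)
        autos = cf.graph_automorphisms(ethanol_graph)
        naive = cf.kabsch_rmsd(s1.positions, s2.positions)
        sym = cf.symmetry_rmsd(s1.positions, s2.positions, autos,
                               include_mirror=False)
        assert sym <= naive + 1e-12

    def test_mirror_detected(self, ethanol_graph):
        s = cf.embed_initial(ethanol_graph, seed=1)
        autos = cf.graph_automorphisms(ethanol_graph)
        mirrored = s.positions * np.array([1.0, 1.0, -1.0])
        d = cf.symmetry_rmsd(s.positions, mirrored, autos,
                             include_mirror=True)
        assert d < 1e-10

    def test_automorphism_count_ethanol(self, ethanol_graph):
        autos = cf.graph_automorphisms(ethanol_graph)
        # 3! (methyl H) x 2! (methylene H) = 12
        assert len(autos) == 12


class TestDeduplicate:
    def _conf(self, s, positions):
        return cf.Conformer(Structure3D(s.atomic_numbers, positions), 0.0,
                            0, 0.0)

    def test_duplicates_collapse(self, ethanol_graph):
        s = cf.embed_initial(ethanol_graph, seed=1)
        confs = [self._conf(s, s.positions.copy()) for _ in range(3)]
        kept = cf.deduplicate(confs, ethanol_graph)
        assert len(kept) == 1

    def test_pose_independence(self, ethanol_graph):
        s = cf.embed_initial(ethanol_graph, seed=1)
        rot = Rotation.from_euler("xyz", [1.1, 0.2, -0.5]).as_matrix()
        moved = s.positions @ rot.T + 5.0
        kept = cf.deduplicate(
            [self._conf(s, s.positions), self._conf(s, moved)],
            ethanol_graph)
        assert len(kept) == 1

    def test_mirror_pair_collapses(self, ethanol_graph):
        s = cf.embed_initial(ethanol_graph, seed=1)
        mirrored = s.positions * np.array([-1.0, 1.0, 1.0])
        kept = cf.deduplicate(
            [self._conf(s, s.positions), self._conf(s, mirrored)],
            ethanol_graph)
        assert len(kept) == 1

    def test_inconsistent_atom_counts(self, ethanol_graph):
        s = cf.embed_initial(ethanol_graph, seed=1)
        other = Structure3D(np.array([1, 1]), np.zeros((2, 3)) + 0.4)
        with pytest.raises(ValueError):
            cf.deduplicate([self._conf(s, s.positions),
                            cf.Conformer(other, 0.0, 0, 0.0)],
                           ethanol_graph)

    def test_keep_first_order_stable(self, ethanol_graph, ethanol_ff):
        s = cf.embed_initial(ethanol_graph, seed=1)
        c1 = cf.local_optimize(s, ethanol_ff)
        confs = [c1, self._conf(s, c1.positions.copy())]
        kept = cf.deduplicate(confs, ethanol_graph)
        assert kept[0] is c1
        assert kept[0].cluster_id == 0


class TestConformerSearch:
    def test_methane_single_conformer(self):
        g = ChemicalGraph.from_smiles("C")
        ff = ToyForceField.from_graph(g)
        c0 = cf.local_optimize(cf.embed_initial(g, seed=1), ff)
        confs = cf.conformer_search(c0, g, ff, seed=1, generations=2)
        assert len(confs) == 1

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_ethanol_two_conformers(self, ethanol_graph, ethanol_ff, seed):
        c0 = cf.local_optimize(cf.embed_initial(ethanol_graph, seed=seed),
                               ethanol_ff)
        confs = cf.conformer_search(c0, ethanol_graph, ethanol_ff,
                                    seed=seed, generations=12)
        assert len(confs) == 2

    def test_every_conformer_satisfies_fmax(self, ethanol_graph,
                                            ethanol_ff):
        c0 = cf.local_optimize(cf.embed_initial(ethanol_graph, seed=2),
                               ethanol_ff)
        confs = cf.conformer_search(c0, ethanol_graph, ethanol_ff, seed=2,
                                    generations=6)
        for c in confs:
            f = ethanol_ff.evaluate(c.structure).forces
            assert np.sqrt((f ** 2).sum(axis=1)).max() < 5e-3


@pytest.mark.slow
class TestButane:
    def test_two_unique_conformers(self):
        g = ChemicalGraph.from_smiles("CCCC")
        ff = ToyForceField.from_graph(g)
        c0 = cf.local_optimize(cf.embed_initial(g, seed=1), ff)
        confs = cf.conformer_search(c0, g, ff, seed=1, generations=12)
        # anti + one gauche (the mirror gauche collapses in dedup)
        assert len(confs) == 2
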