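import numpy as np
import pytest

from glycontact import contacts as ct
from glycontact.io import AtomSet, Topology, Trajectory

from conftest import random_trajectory


def brute_min_distance(coords, idx_a, idx_b):
    best = np.inf
    for i in idx_a:
        for j in idx_b:
            best = min(best, float(np.linalg.norm(coords[i] - coords[j])))
    return best


def single_atom_traj(points, n_frames=1):
    """One residue per atom, all carbon, peptide role."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    top = Topology(
        atom_names=[f"C{i}" for i in range(n)], elements=["C"] * n,
        atom_residue=list(range(n)), res_names=["RES"] * n,
        res_numbers=list(range(1, n + 1)), res_chains=["A"] * n,
        res_roles=["peptide"] * n)
    return Trajectory(top, np.tile(points[None], (n_frames, 1, 1)))


class TestMinDistance:
    def test_three_four_five_triangle(self):
        traj = single_atom_traj([[0, 0, 0], [3, 4, 0]])
        s = ct.min_distance_series(traj, AtomSet([0]), AtomSet([1]))
        assert s.values[0] == pytest.approx(5.0)

    def test_minimum_over_pairs(self):
        traj = single_atom_traj([[0, 0, 0], [10, 0, 0], [2, 0, 0]])
        s = ct.min_distance_series(traj, AtomSet([0, 1]), AtomSet([2]))
        assert s.values[0] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        traj = random_trajectory(rng, n_atoms=40, n_frames=5)
        a = AtomSet(np.arange(0, 20))
        b = AtomSet(np.arange(20, 40))
        s = ct.min_distance_series(traj, a, b)
        for f in range(5):
            assert s.values[f] == pytest.approx(
                brute_min_distance(traj.coords[f], a.indices, b.indices),
                abs=1e-10)

    def test_empty_group_raises(self):
        traj = single_atom_traj([[0, 0, 0]])
        with pytest.raises(ValueError):
            ct.min_distance_series(traj, AtomSet([]), AtomSet([0]))


class TestComDistance:
    def test_unit_weight_centroids(self):
        traj = single_atom_traj([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        s = ct.com_distance_series(traj, AtomSet([0, 1]), AtomSet([2]))
        assert s.values[0] == pytest.approx(15.0)

    def test_identical_groups_zero(self):
        traj = single_atom_traj([[1, 2, 3], [4, 5, 6]])
        s = ct.com_distance_series(traj, AtomSet([0, 1]), AtomSet([0, 1]))
        assert s.values[0] == pytest.approx(0.0)

    def test_bound_series_fluctuates_about_bound_distance(self, coupled_run):
        from glycontact.io import select
        spec, traj, truth = coupled_run
        top = traj.topology
        s = ct.com_distance_series(traj, select(top, "role=peptide"),
                                   select(top, "role=glycan"))
        b = truth.bound.astype(bool)
        assert abs(s.values[b].mean() - spec.bound_distance) < 3.0
        assert s.values[~b].min() > 40.0


class TestBindingCounts:
    def make_pair_at(self, dist):
        return single_atom_traj([[0, 0, 0], [dist, 0, 0]])

    @pytest.mark.parametrize("dist,expect35,expect50", [
        (3.4, 1, 1), (4.0, 0, 1), (3.5, 0, 1)])
    def test_cutoff_conventions(self, dist, expect35, expect50):
        traj = self.make_pair_at(dist)
        pep = AtomSet([0])
        gly = [AtomSet([1])]
        assert ct.bound_glycan_count(traj, pep, gly, 3.5)[0] == expect35
        assert ct.bound_glycan_count(traj, pep, gly, 5.0)[0] == expect50

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(8)
        traj = random_trajectory(rng, n_atoms=30, n_frames=4, scale=6.0)
        pep = AtomSet(np.arange(10))
        gly = [AtomSet(np.arange(10, 20)), AtomSet(np.arange(20, 30))]
        prev = np.zeros(4, dtype=int)
        for cutoff in (1.0, 2.5, 4.0, 8.0, 20.0):
            cur = ct.bound_glycan_count(traj, pep, gly, cutoff)
            assert (cur >= prev).all()
            prev = cur

    def test_indicator_matches_ground_truth(self, coupled_run):
        from glycontact.io import select
        spec, traj, truth = coupled_run
        top = traj.topology
        pep_res = top.residues_with_role("peptide")
        Y = ct.residue_binding_indicators(
            traj, pep_res, select(top, "role=glycan and heavy"), cutoff=3.5)
        b = truth.bound.astype(bool)
        lo, hi = spec.contact_residues
        assert Y[b][:, lo - 1:hi].all()

    def test_indicator_distance_examples(self):
        traj = single_atom_traj([[0, 0, 0], [4.9, 0, 0]])
        Y50 = ct.residue_binding_indicators(traj, np.array([0]), AtomSet([1]), 5.0)
        Y35 = ct.residue_binding_indicators(traj, np.array([0]), AtomSet([1]), 3.5)
        assert Y50[0, 0] == 1 and Y35[0, 0] == 0


class TestSummaryAndMatrices:
    def test_summary_of_known_series(self):
        pts = np.zeros((3, 2, 3))
        pts[:, 1, 0] = [2.0, 4.0, 6.0]
        top = single_atom_traj([[0, 0, 0], [0, 0, 0]]).topology
        traj = Trajectory(top, pts)
        df = ct.residue_min_distance_summary(traj, np.array([0]), AtomSet([1]))
        row = df.loc[1]
        assert row["mean"] == pytest.approx(4.0)
        assert row["median"] == pytest.approx(4.0)

    def test_quartiles_match_numpy_oracle(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(1, 50, 1000)
        pts = np.zeros((1000, 2, 3))
        pts[:, 1, 0] = series
        top = single_atom_traj([[0, 0, 0], [0, 0, 0]]).topology
        traj = Trajectory(top, pts)
        df = ct.residue_min_distance_summary(traj, np.array([0]), AtomSet([1]))
        q1, med, q3 = np.percentile(series, [25, 50, 75])
        assert df.loc[1, "q1"] == pytest.approx(q1)
        assert df.loc[1, "q3"] == pytest.approx(q3)

    def test_ca_matrix_conventions(self):
        # residues with single CA atoms at known separations
        n = 3
        top = Topology(
            atom_names=["CA"] * n, elements=["C"] * n,
            atom_residue=list(range(n)), res_names=["ALA"] * n,
            res_numbers=[1, 2, 3], res_chains=["A"] * n,
            res_roles=["peptide"] * n)
        pts = np.array([[[0, 0, 0], [7.9, 0, 0], [7.9 + 8.0, 0, 0]]])
        traj = Trajectory(top, pts)
        dist, freq = ct.ca_matrices(traj, np.arange(n), cutoff=8.0)
        assert freq.values[0, 1] == 1.0          # 7.9 < 8.0
        assert freq.values[1, 2] == 0.0          # exactly 8.0: strict
        assert freq.values[0, 0] == 1.0
        assert dist.values[0, 0] == 0.0
        assert dist.values[0, 1] == pytest.approx(7.9)

    def test_matrix_difference_antisymmetry(self):
        a = ct.ContactMatrix(np.array([[10.0]]), [1], [1], "mean_distance")
        b = ct.ContactMatrix(np.array([[7.5]]), [1], [1], "mean_distance")
        d1 = ct.matrix_difference(a, b)
        d2 = ct.matrix_difference(b, a)
        assert d1.values[0, 0] == pytest.approx(2.5)
        np.testing.assert_allclose(d1.values, -d2.values)
        same = ct.matrix_difference(a, a)
        assert (same.values == 0).all()

    def test_contact_frequency_is_time_average_of_indicator(self):
        rng = np.random.default_rng(2)
        n = 5
        top = Topology(
            atom_names=["CA"] * n, elements=["C"] * n,
            atom_residue=list(range(n)), res_names=["ALA"] * n,
            res_numbers=list(range(1, n + 1)), res_chains=["A"] * n,
            res_roles=["peptide"] * n)
        coords = rng.uniform(0, 12, size=(20, n, 3))
        traj = Trajectory(top, coords)
        _, freq = ct.ca_matrices(traj, np.arange(n), cutoff=8.0)
        for i in range(n):
            for j in range(n):
                ind = [np.linalg.norm(coords[f, i] - coords[f, j]) < 8.0
                       for f in range(20)]
                assert freq.values[i, j] == pytest.approx(np.mean(ind))


class TestSugarMatrix:
    def make_glycan_traj(self, res_positions):
        """Peptide residue at origin plus one glycan of named sugar beads."""
        names, elems, ares, rn, rnum, rch, rr = (["CA"], ["C"], [0], ["ALA"],
                                                 [1], ["A"], ["peptide"])
        pts = [[0.0, 0.0, 0.0]]
        units = []
        ri = 1
        unit = []
        for code, pos in res_positions:
            rn.append(code)
            rnum.append(ri)
            rch.append("B")
            rr.append("glycan")
            names.append("R1")
            elems.append("C")
            ares.append(ri)
            pts.append(pos)
            unit.append(ri)
            ri += 1
        top = Topology(atom_names=names, elements=elems, atom_residue=ares,
                       res_names=rn, res_numbers=rnum, res_chains=rch,
                       res_roles=rr, glycan_units=[np.array(unit)])
        return Trajectory(top, np.array(pts, dtype=float)[None])

    def test_single_frame_single_copy(self):
        traj = self.make_glycan_traj([("GLC", [2.0, 0, 0])])
        m = ct.residue_sugar_matrix(traj, np.array([0]),
                                    sugar_columns=["Glc"])
        assert m.values[0, 0] == pytest.approx(2.0)

    def test_time_average(self):
        traj = self.make_glycan_traj([("GLC", [2.0, 0, 0])])
        coords = np.concatenate([traj.coords, traj.coords])
        coords[1, 1, 0] = 4.0
        traj2 = Trajectory(traj.topology, coords)
        m = ct.residue_sugar_matrix(traj2, np.array([0]),
                                    sugar_columns=["Glc"])
        assert m.values[0, 0] == pytest.approx(3.0)

    def test_min_over_copies_and_mean_option(self):
        names, elems, ares = ["CA"], ["C"], [0]
        rn, rnum, rch, rr = ["ALA"], [1], ["A"], ["peptide"]
        pts = [[0.0, 0, 0], [3.0, 0, 0], [7.0, 0, 0]]
        for k, chain in enumerate("BC"):
            rn.append("NEU")
            rnum.append(1)
            rch.append(chain)
            rr.append("glycan")
            names.append("R1")
            elems.append("C")
            ares.append(k + 1)
        top = Topology(atom_names=names, elements=elems, atom_residue=ares,
                       res_names=rn, res_numbers=rnum, res_chains=rch,
                       res_roles=rr,
                       glycan_units=[np.array([1]), np.array([2])])
        traj = Trajectory(top, np.array(pts)[None])
        m_min = ct.residue_sugar_matrix(traj, np.array([0]),
                                        sugar_columns=["Neu"], pool="min")
        m_mean = ct.residue_sugar_matrix(traj, np.array([0]),
                                         sugar_columns=["Neu"], pool="mean")
        assert m_min.values[0, 0] == pytest.approx(3.0)
        assert m_mean.values[0, 0] == pytest.approx(5.0)

    def test_unknown_sugar_label_raises(self):
        traj = self.make_glycan_traj([("GLC", [2.0, 0, 0])])
        with pytest.raises(ValueError):
            ct.residue_sugar_matrix(traj, np.array([0]),
                                    sugar_columns=["Xyz"])


class TestEndToEnd:
    def test_straight_chain(self):
        traj = single_atom_traj([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        s = ct.end_to_end_series(traj, AtomSet([0, 1, 2]))
        assert s.values[0] == pytest.approx(10.0)

    def test_coincident_ends(self):
        traj = single_atom_traj([[0, 0, 0], [5, 0, 0], [0, 0, 0]])
        s = ct.end_to_end_series(traj, AtomSet([0, 1, 2]))
        assert s.values[0] == pytest.approx(0.0)

    def test_equals_direct_two_point_distance(self):
        rng = np.random.default_rng(4)
        traj = random_trajectory(rng, n_atoms=10, n_frames=6)
        chain = AtomSet(np.arange(10))
        s = ct.end_to_end_series(traj, chain)
        direct = np.linalg.norm(traj.coords[:, 9] - traj.coords[:, 0], axis=1)
        np.testing.assert_allclose(s.values, direct, atol=1e-12)

    def test_too_short_chain_raises(self):
        traj = single_atom_traj([[0, 0, 0]])
        with pytest.raises(ValueError):
            ct.end_to_end_series(traj, AtomSet([0]))
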