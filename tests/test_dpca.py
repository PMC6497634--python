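import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycontact import dpca
from glycontact.io import Topology, Trajectory


def chain_traj(points):
    points = np.asarray(points, dtype=float)
    n = len(points)
    top = Topology(
        atom_names=[f"C{i}" for i in range(n)], elements=["C"] * n,
        atom_residue=[0] * n, res_names=["LIG"], res_numbers=[1],
        res_chains=["B"], res_roles=["glycan"])
    return Trajectory(top, points[None])


def torsion_oracle(p0, p1, p2, p3):
    """Independent atan2-of-cross/dot torsion (different formulation)."""
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return np.degrees(np.arctan2(m1 @ n2, n1 @ n2))


class TestExtractDihedrals:
    def test_anti_conformation(self):
        pts = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]]
        traj = chain_traj(pts)
        ang = dpca.extract_dihedrals(traj, [(0, 1, 2, 3)])
        assert ang[0, 0] == pytest.approx(180.0)

    def test_eclipsed_conformation(self):
        pts = [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]
        traj = chain_traj(pts)
        ang = dpca.extract_dihedrals(traj, [(0, 1, 2, 3)])
        assert ang[0, 0] == pytest.approx(0.0)

    def test_matches_vector_algebra_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            pts = rng.normal(size=(4, 3)) * 3
            traj = chain_traj(pts)
            ang = dpca.extract_dihedrals(traj, [(0, 1, 2, 3)])[0, 0]
            assert ang == pytest.approx(torsion_oracle(*pts), abs=1e-9)

    def test_collinear_atoms_raise(self):
        pts = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]]
        with pytest.raises(ValueError, match="collinear"):
            dpca.extract_dihedrals(chain_traj(pts), [(0, 1, 2, 3)])


class TestTransform:
    def test_zero_angle(self):
        ds = dpca.transform(np.array([[0.0]]))
        np.testing.assert_allclose(ds.q, [[1.0, 0.0]])

    def test_plus_minus_180_coincide(self):
        ds = dpca.transform(np.array([[180.0], [-180.0]]))
        np.testing.assert_allclose(ds.q[0], ds.q[1], atol=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        angles = rng.uniform(-179.9, 180, size=(50, 3))
        ds = dpca.transform(angles)
        np.testing.assert_allclose(ds.angles(), angles, atol=1e-10)


class TestFit:
    def test_degenerate_dataset_has_zero_eigenvalues(self):
        q = np.tile([0.6, 0.8], (5, 1))
        model = dpca.fit(q)
        np.testing.assert_allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_two_point_dataset_hand_covariance(self):
        model = dpca.fit(np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(model.eigenvalues, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(model.eigenvectors[:, 0]),
                                   [1.0, 0.0], atol=1e-12)

    def test_population_normalization(self):
        rng = np.random.default_rng(0)
        q = rng.normal(size=(100, 4))
        model = dpca.fit(q)
        cov = np.cov(q.T, bias=True)       # 1/M
        assert model.eigenvalues.sum() == pytest.approx(np.trace(cov),
                                                        abs=1e-8)

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(5)
        q = rng.normal(size=(60, 4))
        m1 = dpca.fit(q)
        m2 = dpca.fit(q[::-1])
        np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(m1.eigenvectors, m2.eigenvectors,
                                   atol=1e-8)

    def test_single_observation_raises(self):
        with pytest.raises(ValueError):
            dpca.fit(np.array([[1.0, 0.0]]))


class TestProject:
    def test_one_dimensional_hand_example(self):
        model = dpca.fit(np.array([[0.0], [2.0]]))
        proj = dpca.project(model, np.array([[0.0], [2.0]]))
        # mean 1, eigenvector +1 by sign convention -> projections -1, +1
        np.testing.assert_allclose(proj[:, 0], [-1.0, 1.0], atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_spectral_identities_and_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-180, 180, size=(40, 3))
        ds = dpca.transform(angles)
        model = dpca.fit(ds)
        proj = dpca.project(model, ds)
        np.testing.assert_allclose(proj.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(proj.var(axis=0), model.eigenvalues,
                                   atol=1e-8)
        recon = proj @ model.eigenvectors.T
        np.testing.assert_allclose(recon, ds.q - model.mean, atol=1e-8)

    def test_dimension_mismatch_raises(self):
        model = dpca.fit(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="columns"):
            dpca.project(model, np.zeros((3, 6)))


def two_blob_projections(n=5000, w=0.7, seed=0):
    rng = np.random.default_rng(seed)
    labels = rng.random(n) < w
    angles = np.where(labels, rng.normal(60.0, 3.0, n),
                      rng.normal(180.0, 3.0, n))
    ds = dpca.transform(angles[:, None])
    model = dpca.fit(ds)
    return dpca.project(model, ds), labels


class TestDensityMap:
    def test_single_blob_one_mode(self):
        rng = np.random.default_rng(3)
        angles = rng.normal(60.0, 2.0, 5000)
        ds = dpca.transform(angles[:, None])
        proj = dpca.project(dpca.fit(ds), ds)
        cmap = dpca.density_map(proj, bins=30)
        assert cmap.n_modes == 1
        assert cmap.mode_populations[0] >= 0.99

    def test_two_blobs_populations_match_weights(self):
        proj, labels = two_blob_projections()
        cmap = dpca.density_map(proj, bins=40)
        assert cmap.n_modes == 2
        pops = np.sort(cmap.mode_populations)[::-1]
        se = np.sqrt(0.7 * 0.3 / 5000)
        assert abs(pops[0] - 0.7) < 3 * se + 0.01
        assert abs(pops[1] - 0.3) < 3 * se + 0.01

    def test_mode_count_stable_under_bin_doubling(self):
        proj, _ = two_blob_projections()
        m1 = dpca.density_map(proj, bins=30)
        m2 = dpca.density_map(proj, bins=60)
        assert m1.n_modes == m2.n_modes == 2

    def test_all_below_absolute_floor_is_noise(self):
        rng = np.random.default_rng(8)
        proj = rng.uniform(-1, 1, size=(500, 2))
        cmap = dpca.density_map(proj, bins=10, min_count=10_000)
        assert cmap.n_modes == 0
        assert (cmap.point_mode == -1).all()

    def test_zero_width_axis_raises(self):
        with pytest.raises(ValueError, match="zero-width"):
            dpca.density_map(np.zeros((10, 2)))


class TestKmeansModes:
    def test_two_blob_weights_and_determinism(self):
        proj, _ = two_blob_projections()
        labels, pops = dpca.kmeans_modes(proj, k=2, seed=3)
        labels2, pops2 = dpca.kmeans_modes(proj, k=2, seed=3)
        np.testing.assert_array_equal(labels, labels2)
        np.testing.assert_allclose(np.sort(pops), [0.3, 0.7], atol=0.02)


class TestConditionalDensity:
    def test_always_true_condition_reproduces_full_map(self):
        proj, _ = two_blob_projections(n=2000)
        full, cond = dpca.conditional_density(proj, np.ones(2000, dtype=bool))
        np.testing.assert_array_equal(full.counts, cond.counts)
        np.testing.assert_allclose(full.mode_populations,
                                   cond.mode_populations)

    def test_condition_restricted_to_one_mode(self):
        proj, labels = two_blob_projections(n=2000)
        full, cond = dpca.conditional_density(proj, labels)
        # conditioning on blob-1 membership empties the other mode
        assert cond.mode_populations.min() < 0.01
        assert cond.mode_populations.max() > 0.95

    def test_halved_mode_weight_recovered(self):
        # binding suppresses blob 2 by half: weights (0.7, 0.3) -> conditional
        # keep probability 0.5 for blob-2 points
        rng = np.random.default_rng(12)
        proj, labels = two_blob_projections(n=6000, w=0.7, seed=11)
        keep = np.where(labels, True, rng.random(6000) < 0.5)
        full, cond = dpca.conditional_density(proj, keep)
        # blob-2 conditional population should be near 0.15/0.85
        expect = 0.15 / 0.85
        small = cond.mode_populations.min()
        se = 3 * np.sqrt(expect * (1 - expect) / keep.sum())
        assert abs(small - expect) < 3 * se + 0.01

    def test_misaligned_lengths_raise(self):
        with pytest.raises(ValueError, match="length"):
            dpca.conditional_density(np.zeros((10, 2)), np.ones(5))
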