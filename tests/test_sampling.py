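import numpy as np
import pytest

from toro_indexer import (
    BasisMatrix,
    ReciprocalSpots,
    UnitCell,
    attach_and_spin,
    basis_scores,
    cell_from_basis,
    laue_closeness_scores,
    random_rotation,
    rank_and_keep,
    real_from_reciprocal,
    reciprocal_basis_from_cell,
    sample_sphere,
)
from toro_indexer.errors import ParameterError


class TestSampleSphere:
    def test_single_point_has_requested_radius(self):
        pts = sample_sphere(1, 7.0)
        assert pts.shape == (1, 3)
        assert np.linalg.norm(pts[0]) == pytest.approx(7.0, rel=1e-12)

    def test_norms_and_uniqueness(self):
        pts = sample_sphere(1000, 1.0)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, rtol=1e-9)
        assert len(np.unique(np.round(pts, 12), axis=0)) == 1000

    def test_deterministic(self):
        np.testing.assert_array_equal(sample_sphere(500, 2.5), sample_sphere(500, 2.5))

    def test_quasi_uniform_nearest_neighbour_spacing(self):
        # brute-force all-pairs great-circle distances
        pts = sample_sphere(1000, 1.0)
        dots = np.clip(pts @ pts.T, -1.0, 1.0)
        np.fill_diagonal(dots, -1.0)
        nn = np.arccos(dots.max(axis=1))
        assert nn.max() <= 2.0 * nn.min()

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            sample_sphere(0, 1.0)
        with pytest.raises(ParameterError):
            sample_sphere(10, -1.0)


class TestLaueCloseness:
    def test_integer_products_score_full(self):
        spots = ReciprocalSpots([[0.1, 0, 0], [0.2, 0, 0]])
        score = laue_closeness_scores(spots, np.array([[10.0, 0, 0]]))
        assert score[0] == pytest.approx(2.0, abs=1e-12)

    def test_half_integer_product_scores_zero(self):
        spots = ReciprocalSpots([[0.05, 0, 0]])
        score = laue_closeness_scores(spots, np.array([[10.0, 0, 0]]))
        assert score[0] == pytest.approx(0.0, abs=1e-12)

    def test_random_spots_score_half_on_average(self):
        # oracle: direct summation of the kernel over the spots
        rng = np.random.default_rng(5)
        s = rng.uniform(-1, 1, size=(50, 3))
        s = s[np.linalg.norm(s, axis=1) <= 1.0]
        spots = ReciprocalSpots(s)
        v = rng.normal(size=3) * 20
        t = s @ v
        frac = t - np.rint(t)
        oracle = np.sum(0.5 * (1 + np.cos(2 * np.pi * frac)))
        score = laue_closeness_scores(spots, v[None, :])
        assert score[0] == pytest.approx(oracle, rel=1e-12)
        assert abs(score[0] - len(s) / 2) < 0.35 * len(s)  # sampling error band

    def test_padding_rows_excluded(self):
        spots = ReciprocalSpots(
            [[0.1, 0, 0], [0.33, 0, 0]], mask=[True, False]
        )
        score = laue_closeness_scores(spots, np.array([[10.0, 0, 0]]))
        assert score[0] == pytest.approx(1.0, abs=1e-12)

    def test_empty_frame_scores_zero(self):
        spots = ReciprocalSpots(np.empty((0, 3)))
        assert laue_closeness_scores(spots, np.eye(3))[0] == 0.0


class TestRankAndKeep:
    def test_top_k(self):
        np.testing.assert_array_equal(rank_and_keep(np.array([3.0, 1.0, 2.0]), 2), [0, 2])

    def test_stable_ties(self):
        np.testing.assert_array_equal(rank_and_keep(np.ones(4), 2), [0, 1])

    def test_k_exceeding_size_returns_all(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10)
        assert sorted(rank_and_keep(scores, 99)) == list(range(10))


class TestAttachAndSpin:
    def test_identity_attachment_returns_b0(self, cell):
        b0 = reciprocal_basis_from_cell(cell)
        a0 = real_from_reciprocal(b0).matrix
        bases = attach_and_spin(a0[:, 0], b0, "a", 8)
        np.testing.assert_allclose(bases[0], b0.matrix, atol=1e-12)

    def test_snapshots_are_rigid_copies(self, triclinic_cell):
        b0 = reciprocal_basis_from_cell(triclinic_cell)
        v = random_rotation(11) @ real_from_reciprocal(b0).matrix[:, 1]
        bases = attach_and_spin(v, b0, "b", 12)
        g0 = b0.matrix.T @ b0.matrix
        for mat in bases:
            np.testing.assert_allclose(mat.T @ mat, g0, rtol=1e-8)
            fitted = cell_from_basis(BasisMatrix(mat, "reciprocal"))
            np.testing.assert_allclose(fitted.lengths, triclinic_cell.lengths, rtol=1e-6)
            np.testing.assert_allclose(fitted.angles, triclinic_cell.angles, rtol=1e-6)

    def test_attached_axis_fixed_during_spin(self, cell):
        b0 = reciprocal_basis_from_cell(cell)
        v = random_rotation(7) @ real_from_reciprocal(b0).matrix[:, 2]
        bases = attach_and_spin(v, b0, "c", 10)
        for mat in bases:
            real = np.linalg.inv(mat).T
            np.testing.assert_allclose(real[:, 2], v, atol=1e-9)

    def test_four_snapshot_cubic_spin(self):
        # oracle: explicit 90-degree rotations about +x
        cell = UnitCell(10, 10, 10, 90, 90, 90, "cubic")
        b0 = reciprocal_basis_from_cell(cell)
        bases = attach_and_spin(np.array([10.0, 0, 0]), b0, "a", 4)
        b_vectors = {
            tuple(np.round(np.linalg.inv(m).T[:, 1], 9)) for m in bases
        }
        expected = {(0.0, 10.0, 0.0), (0.0, 0.0, 10.0), (0.0, -10.0, 0.0),
                    (0.0, 0.0, -10.0)}
        assert b_vectors == expected

    def test_zero_vector_rejected(self, cell):
        b0 = reciprocal_basis_from_cell(cell)
        with pytest.raises(ParameterError):
            attach_and_spin(np.zeros(3), b0, "a", 4)


class TestBasisScores:
    def test_ground_truth_scores_full(self, cell, geom):
        from toro_indexer import simulate_frame

        fr = simulate_frame(cell, geom, n_spots=30, seed=2)
        score = basis_scores(fr.spots, fr.true_basis.matrix[None])
        assert score[0] == pytest.approx(30.0, abs=1e-9)

    def test_all_masked_scores_zero(self, cell):
        spots = ReciprocalSpots(np.zeros((5, 3)), mask=np.zeros(5, dtype=bool))
        b0 = reciprocal_basis_from_cell(cell)
        assert basis_scores(spots, b0.matrix[None])[0] == 0.0

    def test_singular_basis_scores_minus_inf(self, cell, geom):
        from toro_indexer import simulate_frame

        fr = simulate_frame(cell, geom, n_spots=20, seed=3)
        assert basis_scores(fr.spots, np.zeros((1, 3, 3)))[0] == -np.inf

    def test_truth_beats_random_orientations(self, cell, geom):
        # Monte-Carlo: truth must outscore a random orientation essentially always
        from toro_indexer import simulate_frame

        wins = 0
        trials = 40
        for i in range(trials):
            fr = simulate_frame(cell, geom, n_spots=60, seed=100 + i)
            truth = basis_scores(fr.spots, fr.true_basis.matrix[None])[0]
            rand = basis_scores(
                fr.spots, (random_rotation(500 + i) @ fr.true_basis.matrix)[None]
            )[0]
            wins += truth > rand
        assert wins >= trials - 1


def test_candidate_coverage_induces_mostly_correct_indices(cell, geom):
    """For a noise-free frame some top-ranked candidate basis must induce
    >= 80% correct Miller indices (up to a lattice re-basis, checked via
    residuals of the induced assignment)."""
    from toro_indexer import IndexerParams, induced_miller, residual_norms
    from toro_indexer.indexer import _candidate_bases
    from toro_indexer import BasisMatrix, simulate_frame

    fr = simulate_frame(cell, geom, n_spots=30, seed=9)
    params = IndexerParams.from_preset("rt")  # lattice_size 10000
    bases = _candidate_bases(fr.spots, cell, params)
    best = 0.0
    for mat in bases:
        b = BasisMatrix(mat, "reciprocal")
        hkl = induced_miller(b, fr.spots)
        res = residual_norms(b, hkl, fr.spots)
        # an induced index is "correct enough" if it reproduces the spot
        # to within a quarter of the smallest lattice spacing
        good = np.mean(res < 0.25 * np.linalg.norm(mat, axis=0).min())
        best = max(best, good)
    assert best >= 0.8
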