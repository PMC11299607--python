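import numpy as np
import pytest

from toro_indexer import (
    BasisMatrix,
    IndexerParams,
    IndexingSolution,
    MillerAssignment,
    ReciprocalSpots,
    bases_equivalent,
    cell_penalty,
    index_batch,
    index_frame,
    metrics_equivalent,
    prune_and_pad,
    random_rotation,
    reciprocal_basis_from_cell,
    select_solutions,
    simulate_frame,
)


class TestPruneAndPad:
    def test_keeps_lowest_resolution_spots(self, cell, geom):
        fr = simulate_frame(cell, geom, n_spots=100, seed=1, s_max=0.45)
        batch = prune_and_pad([fr.spots], 80)
        kept = batch.spots[0][batch.mask[0]]
        # oracle: full sort of |s|
        norms = np.sort(np.linalg.norm(fr.spots.s, axis=1))
        np.testing.assert_allclose(
            np.sort(np.linalg.norm(kept, axis=1)), norms[:80], rtol=1e-12
        )
        # rows ordered by ascending |s|
        assert np.all(np.diff(np.linalg.norm(kept, axis=1)) >= 0)

    def test_small_frame_zero_padded(self, cell, geom):
        fr = simulate_frame(cell, geom, n_spots=50, seed=2)
        batch = prune_and_pad([fr.spots], 80)
        assert batch.mask[0].sum() == 50
        np.testing.assert_array_equal(batch.spots[0][~batch.mask[0]], 0.0)

    def test_exact_size_identity_content(self, cell, geom):
        fr = simulate_frame(cell, geom, n_spots=80, seed=3, s_max=0.45)
        batch = prune_and_pad([fr.spots], 80)
        assert batch.mask[0].all()
        got = set(map(tuple, np.round(batch.spots[0], 12)))
        want = set(map(tuple, np.round(fr.spots.s, 12)))
        assert got == want


class TestCellPenalty:
    def test_rigid_rotation_has_zero_penalty(self, cell):
        b0 = reciprocal_basis_from_cell(cell)
        rot = BasisMatrix(random_rotation(5) @ b0.matrix)
        penalty, valid = cell_penalty(rot, cell, 0.05, 3.0)
        assert penalty == pytest.approx(0.0, abs=1e-9)
        assert valid

    def test_stretched_axis_fails_tolerance(self, cell):
        b0 = reciprocal_basis_from_cell(cell)
        mat = b0.matrix.copy()
        mat[:, 0] /= 1.10  # real-space a stretched by 1.10
        penalty, valid = cell_penalty(BasisMatrix(mat), cell, 0.05, 3.0)
        assert not valid
        assert penalty > 0.05

    def test_penalty_matches_hand_computed_sum(self, cell):
        from toro_indexer import cell_from_basis

        rng = np.random.default_rng(8)
        mat = reciprocal_basis_from_cell(cell).matrix + rng.normal(scale=2e-4, size=(3, 3))
        basis = BasisMatrix(mat)
        fitted = cell_from_basis(basis)
        expected = float(
            np.sum(np.abs(fitted.lengths - cell.lengths) / cell.lengths)
            + np.sum(np.abs(fitted.angles - cell.angles) / 90.0)
        )
        penalty, _ = cell_penalty(basis, cell, 0.05, 3.0)
        assert penalty == pytest.approx(expected, abs=1e-12)


def _mock_solution(basis, mask, penalty, frame_id="f"):
    m = len(mask)
    return IndexingSolution(
        basis=basis,
        hkl=MillerAssignment(np.zeros((m, 3), dtype=int)),
        inlier_mask=np.asarray(mask, dtype=bool),
        residual_norms=np.zeros(m),
        num_inliers=int(np.sum(mask)),
        penalty=penalty,
        accepted=True,
        frame_id=frame_id,
    )


class TestSelectSolutions:
    def test_single_candidate_returned(self, cell, desk_params):
        b0 = reciprocal_basis_from_cell(cell)
        sol = _mock_solution(b0, [True] * 10, 0.01)
        assert select_solutions([sol], desk_params) == [sol]

    def test_penalty_breaks_inlier_ties(self, cell, desk_params):
        b0 = reciprocal_basis_from_cell(cell)
        lo = _mock_solution(b0, [True] * 10 + [False] * 10, 0.01)
        hi = _mock_solution(b0, [False] * 10 + [True] * 10, 0.03)
        assert select_solutions([hi, lo], desk_params)[0] is lo

    def test_overlapping_candidates_suppressed(self, cell, desk_params):
        b0 = reciprocal_basis_from_cell(cell)
        a = _mock_solution(b0, [True] * 12 + [False] * 8, 0.01)
        b = _mock_solution(b0, [True] * 10 + [False] * 10, 0.02)  # subset of a
        c = _mock_solution(b0, [False] * 12 + [True] * 8, 0.02)  # disjoint
        got = select_solutions([a, b, c], desk_params)
        assert got == [a, c]


class TestIndexFrame:
    def test_noise_free_frame_recovers_metric(self, cell, geom, desk_params):
        fr = simulate_frame(cell, geom, n_spots=40, seed=21)
        sols = index_frame(fr.spots, cell, desk_params)
        assert len(sols) == 1
        sol = sols[0]
        g0 = reciprocal_basis_from_cell(cell).matrix
        assert metrics_equivalent(
            sol.basis.matrix.T @ sol.basis.matrix, g0.T @ g0, tol=1e-4
        )
        assert bases_equivalent(sol.basis, fr.true_basis, tol=1e-3)

    def test_empty_frame_gives_empty_result(self, cell, desk_params):
        spots = ReciprocalSpots(np.empty((0, 3)))
        assert index_frame(spots, cell, desk_params) == []

    def test_below_kmin_gives_empty_result(self, cell, geom, desk_params):
        fr = simulate_frame(cell, geom, n_spots=5, seed=22)
        assert index_frame(fr.spots, cell, desk_params) == []

    def test_deterministic(self, cell, noisy_frame, desk_params):
        a = index_frame(noisy_frame.spots, cell, desk_params)
        b = index_frame(noisy_frame.spots, cell, desk_params)
        assert len(a) == len(b) == 1
        np.testing.assert_array_equal(a[0].basis.matrix, b[0].basis.matrix)
        np.testing.assert_array_equal(a[0].inlier_mask, b[0].inlier_mask)

    def test_two_crystal_frame_yields_two_lattices(self, cell, geom, desk_params):
        fr = simulate_frame(
            cell, geom, n_spots=60, n_crystals=2,
            noise_sigma=0.25 * desk_params.max_error_beta, seed=23,
        )
        sols = index_frame(fr.spots, cell, desk_params)
        assert len(sols) == 2
        matched = set()
        for sol in sols:
            for ci, tb in enumerate(fr.true_bases):
                if bases_equivalent(sol.basis, tb, tol=0.01):
                    matched.add(ci)
                    # inliers belong to the matched crystal
                    assert np.all(fr.crystal_id[sol.inlier_mask] == ci)
        assert matched == {0, 1}


class TestIndexBatch:
    def test_batch_equals_per_frame(self, cell, geom, desk_params):
        beta = desk_params.max_error_beta
        frames = [
            simulate_frame(cell, geom, n_spots=n, noise_sigma=0.25 * beta,
                           outlier_fraction=0.1, seed=30 + i).spots
            for i, n in enumerate((40, 30, 50))
        ]
        batch = prune_and_pad(frames, desk_params.max_spots)
        batched = index_batch(batch, cell, desk_params)
        for i in range(len(batch)):
            single = index_frame(batch.frame(i), cell, desk_params)
            assert len(batched[i]) == len(single)
            for bs, ss in zip(batched[i], single):
                np.testing.assert_array_equal(bs.basis.matrix, ss.basis.matrix)
                np.testing.assert_array_equal(bs.inlier_mask, ss.inlier_mask)

    def test_duplicated_frame_gives_identical_solutions(self, cell, noisy_frame,
                                                        desk_params):
        batch = prune_and_pad([noisy_frame.spots, noisy_frame.spots], 40)
        res = index_batch(batch, cell, desk_params)
        assert len(res[0]) == len(res[1]) == 1
        np.testing.assert_array_equal(res[0][0].basis.matrix, res[1][0].basis.matrix)

    def test_all_padding_frame_is_empty_and_isolated(self, cell, noisy_frame,
                                                     desk_params):
        empty = ReciprocalSpots(np.empty((0, 3)), frame_id="empty")
        batch = prune_and_pad([noisy_frame.spots, empty], 40)
        res = index_batch(batch, cell, desk_params)
        assert res[1] == []
        assert len(res[0]) == 1

    def test_padding_rows_never_inliers(self, cell, noisy_frame, desk_params):
        batch = prune_and_pad([noisy_frame.spots], 60)  # 20 padded rows
        res = index_batch(batch, cell, desk_params)
        sol = res[0][0]
        assert not np.any(sol.inlier_mask[~batch.mask[0]])

    def test_padding_neutrality(self, cell, noisy_frame, desk_params):
        plain = prune_and_pad([noisy_frame.spots], 40)
        padded = prune_and_pad([noisy_frame.spots], 55)
        a = index_frame(plain.frame(0), cell, desk_params)[0]
        b = index_frame(padded.frame(0), cell, desk_params)[0]
        np.testing.assert_array_equal(a.basis.matrix, b.basis.matrix)
        np.testing.assert_array_equal(a.inlier_mask, b.inlier_mask[:40])
        assert not b.inlier_mask[40:].any()


def test_quality_preset_never_worse_than_rt(cell, geom):
    """The full-quality settings must index at least as many frames of a
    fixed synthetic suite as the real-time settings (speed/quality knob).
    Both presets are scaled down uniformly to keep the suite quick."""
    rt = IndexerParams.from_preset("rt", lattice_size=1000, num_top_solutions=10)
    full = IndexerParams.from_preset("full", lattice_size=5000, angle_resolution=150,
                                     num_top_solutions=40)
    beta = rt.max_error_beta
    frames = [
        simulate_frame(cell, geom, n_spots=40, noise_sigma=0.25 * beta,
                       outlier_fraction=0.2, seed=900 + i)
        for i in range(10)
    ]
    def rate(params):
        return sum(
            bool(
                (sols := index_frame(fr.spots, cell, params))
                and bases_equivalent(sols[0].basis, fr.true_basis, tol=0.01)
            )
            for fr in frames
        )
    assert rate(full) >= rate(rt)
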