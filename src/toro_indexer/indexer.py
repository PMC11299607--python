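"""Frame and batch orchestration of the full indexing pipeline.

Per frame: sample candidate vectors on per-axis spheres, rank by Laue
closeness, attach and spin basis copies, rank the bases, run the robust
annealed fit on each of the top candidates, penalise fitted cells that
deviate from the ideal cell shape, and greedily select near-disjoint
solutions (multi-lattice frames yield several).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .cell import (
    BasisMatrix,
    ReciprocalSpots,
    UnitCell,
    cell_from_basis,
    reciprocal_basis_from_cell,
    real_from_reciprocal,
)
from .fitting import IndexingSolution, anneal_fit
from .params import IndexerParams
from .sampling import (
    attach_and_spin,
    basis_scores,
    laue_closeness_scores,
    rank_and_keep,
    sample_sphere,
)

__all__ = [
    "FrameBatch",
    "prune_and_pad",
    "cell_penalty",
    "select_solutions",
    "index_frame",
    "index_batch",
]


@dataclass(frozen=True)
class FrameBatch:
    """Fixed-size stack of frames: spots B x max_spots x 3, mask B x max_spots."""

    spots: np.ndarray
    mask: np.ndarray
    frame_ids: tuple

    def __post_init__(self) -> None:
        spots = np.asarray(self.spots, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if spots.ndim != 3 or spots.shape[2] != 3:
            raise ValueError("spots must be B x max_spots x 3")
        if mask.shape != spots.shape[:2]:
            raise ValueError("mask shape must match spots")
        spots = spots.copy()
        spots.setflags(write=False)
        mask = mask.copy()
        mask.setflags(write=False)
        object.__setattr__(self, "spots", spots)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "frame_ids", tuple(self.frame_ids))

    def __len__(self) -> int:
        return len(self.spots)

    def frame(self, i: int) -> ReciprocalSpots:
        return ReciprocalSpots(self.spots[i], self.mask[i], self.frame_ids[i])


def prune_and_pad(frames: Sequence[ReciprocalSpots], max_spots: int) -> FrameBatch:
    """Fix every frame to exactly ``max_spots`` rows.

    Frames with more spots keep the ``max_spots`` of smallest |s| (lowest
    resolution); smaller frames are zero-padded with mask False.  Rows are
    ordered by ascending |s|.
    """
    if max_spots < 1:
        raise ValueError("max_spots must be >= 1")
    b = len(frames)
    spots = np.zeros((b, max_spots, 3))
    mask = np.zeros((b, max_spots), dtype=bool)
    ids = []
    for i, fr in enumerate(frames):
        ids.append(fr.frame_id)
        s = fr.valid()
        order = np.argsort(np.linalg.norm(s, axis=1), kind="stable")
        s = s[order][:max_spots]
        spots[i, : len(s)] = s
        mask[i, : len(s)] = True
    return FrameBatch(spots, mask, tuple(ids))


def cell_penalty(
    basis: BasisMatrix,
    cell: UnitCell,
    length_tol: float,
    angle_tol: float,
) -> tuple[float, bool]:
    """Shape deviation of a fitted basis from the ideal cell.

    penalty = sum_i |len_i - ideal_i| / ideal_i + sum_j |ang_j - ideal_j| / 90;
    valid iff every relative length deviation <= length_tol and every angle
    deviation <= angle_tol degrees.
    """
    fitted = cell_from_basis(basis)
    dlen = np.abs(fitted.lengths - cell.lengths) / cell.lengths
    dang = np.abs(fitted.angles - cell.angles)
    penalty = float(dlen.sum() + (dang / 90.0).sum())
    valid = bool(np.all(dlen <= length_tol) and np.all(dang <= angle_tol))
    return penalty, valid


def select_solutions(
    candidates: Sequence[IndexingSolution], params: IndexerParams
) -> List[IndexingSolution]:
    """Rank accepted candidates and greedily keep near-disjoint lattices.

    Candidates failing the cell-shape check are dropped; the rest are
    ordered by (num_inliers desc, penalty asc) and emitted while each new
    solution shares < 50% of its inliers with every one already emitted, up
    to ``max_lattices`` solutions.
    """
    valid = [c for c in candidates if c.accepted]
    order = sorted(range(len(valid)), key=lambda i: (-valid[i].num_inliers, valid[i].penalty))
    chosen: List[IndexingSolution] = []
    for i in order:
        cand = valid[i]
        if any(
            np.sum(cand.inlier_mask & got.inlier_mask) >= 0.5 * cand.num_inliers
            for got in chosen
        ):
            continue
        chosen.append(cand)
        if len(chosen) >= params.max_lattices:
            break
    return chosen


def _candidate_bases(
    spots: ReciprocalSpots, cell: UnitCell, params: IndexerParams
) -> np.ndarray:
    """Phase 1 + 2: top-scoring rigid candidate bases, T' x 3 x 3."""
    b0 = reciprocal_basis_from_cell(cell)
    a0_real = real_from_reciprocal(b0).matrix
    lengths = np.linalg.norm(a0_real, axis=0)

    # near-equal cell lengths share one sampled sphere (scaled), avoiding
    # triplicated work for (pseudo)cubic cells
    groups: list[list[int]] = []
    for idx in range(3):
        for g in groups:
            if abs(lengths[idx] - lengths[g[0]]) <= 1e-9 * lengths[g[0]]:
                g.append(idx)
                break
        else:
            groups.append([idx])

    axis_names = ("a", "b", "c")
    all_bases = []
    for g in groups:
        radius = lengths[g[0]]
        vectors = sample_sphere(params.lattice_size, radius)
        scores = laue_closeness_scores(spots, vectors, params.score_kernel)
        top = rank_and_keep(scores, params.num_top_vectors)
        for axis_idx in g:
            axis_scale = lengths[axis_idx] / radius  # 1 within a group
            for vi in top:
                v = vectors[vi] * axis_scale
                all_bases.append(
                    attach_and_spin(v, b0, axis_names[axis_idx], params.angle_resolution)
                )
    bases = np.concatenate(all_bases, axis=0)
    bscores = basis_scores(spots, bases, params.score_kernel)
    keep = rank_and_keep(bscores, params.num_top_solutions)
    return bases[keep]


def index_frame(
    spots: ReciprocalSpots, cell: UnitCell, params: IndexerParams
) -> List[IndexingSolution]:
    """Index one frame; returns up to ``max_lattices`` accepted solutions.

    Deterministic given the parameters: the pipeline contains no source of
    randomness.  Returns an empty list (not an exception) when the frame
    has too few spots or no candidate passes the acceptance conditions.
    """
    if spots.n_valid < params.min_spots_kmin:
        return []
    bases = _candidate_bases(spots, cell, params)
    fitted: List[IndexingSolution] = []
    for mat in bases:
        sol = anneal_fit(spots, BasisMatrix(mat, space="reciprocal"), params)
        if sol is None:
            continue
        penalty, shape_ok = cell_penalty(sol.basis, cell, params.length_tol, params.angle_tol)
        sol = IndexingSolution(
            basis=sol.basis,
            hkl=sol.hkl,
            inlier_mask=sol.inlier_mask,
            residual_norms=sol.residual_norms,
            num_inliers=sol.num_inliers,
            penalty=penalty,
            accepted=sol.accepted and shape_ok,
            frame_id=sol.frame_id,
            history=sol.history,
        )
        fitted.append(sol)
    return select_solutions(fitted, params)


def index_batch(
    batch: FrameBatch, cell: UnitCell, params: IndexerParams
) -> List[List[IndexingSolution]]:
    """Index every frame of a batch.

    Semantically identical to calling :func:`index_frame` on each frame;
    padding rows are mask-false throughout and can never become inliers.
    """
    return [index_frame(batch.frame(i), cell, params) for i in range(len(batch))]
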