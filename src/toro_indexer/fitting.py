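"""Robust closed-form basis fitting with residual-threshold annealing.

Given a candidate orientation of the ideal basis, the fractional Miller
coordinates of every reciprocal spot are rounded to integers ("induced"
Miller indices) and the basis that best maps those integers onto the spots
is recovered in closed form from the normal equations of

    min_A  sum_q | A hkl_q - s_q |^2 .

Outliers are handled by a dual variant of least trimmed squares: rounds of
fit / residual-sort / trim, with the inclusion threshold annealed
monotonically down to the acceptance bound beta.  A solution must keep at
least ``min_spots_kmin`` spots, otherwise the frame has no valid solution
for this candidate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cell import BasisMatrix, ReciprocalSpots
from .errors import DegenerateAssignmentError, SingularBasisError
from .params import IndexerParams

__all__ = [
    "MillerAssignment",
    "AnnealState",
    "IndexingSolution",
    "induced_miller",
    "ls_fit_basis",
    "residual_norms",
    "anneal_fit",
]

# annealing schedule: threshold starts at START_FACTOR * beta and is
# multiplied by DECAY each round until it reaches beta exactly
ANNEAL_START_FACTOR = 5.0
ANNEAL_DECAY = 0.7
# extra fit/trim rounds at threshold == beta until the inlier set stabilises
_MAX_FINAL_ROUNDS = 10


@dataclass(frozen=True)
class MillerAssignment:
    """Per-spot integer Miller indices, frame-aligned with the spot mask."""

    hkl: np.ndarray  # m x 3 ints; padding rows all zero

    def __post_init__(self) -> None:
        hkl = np.atleast_2d(np.asarray(self.hkl))
        if hkl.size == 0:
            hkl = hkl.reshape(0, 3)
        if hkl.ndim != 2 or hkl.shape[1] != 3:
            raise ValueError("hkl must be an m x 3 array")
        hkl = hkl.astype(np.int64, copy=True)
        hkl.setflags(write=False)
        object.__setattr__(self, "hkl", hkl)

    def __len__(self) -> int:
        return len(self.hkl)


@dataclass(frozen=True)
class AnnealState:
    """Snapshot of one annealing round (for diagnostics and testing)."""

    round: int
    threshold: float  # 1/angstrom
    active_set: np.ndarray  # bool mask over spots
    loss: float  # least-squares loss on the set the fit used


@dataclass(frozen=True)
class IndexingSolution:
    """One fitted lattice for a frame."""

    basis: BasisMatrix  # reciprocal, fitted
    hkl: MillerAssignment
    inlier_mask: np.ndarray  # bools, the final good set
    residual_norms: np.ndarray  # m floats (inf on padding)
    num_inliers: int
    penalty: float = float("nan")
    accepted: bool = False
    frame_id: str = ""
    history: tuple = ()  # tuple[AnnealState, ...]

    def __post_init__(self) -> None:
        mask = np.asarray(self.inlier_mask, dtype=bool).copy()
        mask.setflags(write=False)
        object.__setattr__(self, "inlier_mask", mask)
        res = np.asarray(self.residual_norms, dtype=float).copy()
        res.setflags(write=False)
        object.__setattr__(self, "residual_norms", res)


def _check_basis(basis: BasisMatrix) -> np.ndarray:
    mat = basis.matrix if isinstance(basis, BasisMatrix) else np.asarray(basis, float)
    det = np.linalg.det(mat)
    if not np.isfinite(det) or abs(det) < 1e-300:
        raise SingularBasisError("singular reciprocal basis")
    return mat


def induced_miller(basis: BasisMatrix, spots: ReciprocalSpots) -> MillerAssignment:
    """Round the fractional coordinates ``B^-1 s_q`` to integer hkl.

    Rounding is componentwise with ties to even (numpy rint semantics);
    padding rows are (0, 0, 0).
    """
    mat = _check_basis(basis)
    hkl = np.zeros((len(spots), 3), dtype=np.int64)
    if spots.mask.any():
        frac = np.linalg.solve(mat, spots.s[spots.mask].T).T
        hkl[spots.mask] = np.rint(frac).astype(np.int64)
    return MillerAssignment(hkl)


def ls_fit_basis(
    spots: ReciprocalSpots, hkl: MillerAssignment, active: np.ndarray
) -> BasisMatrix:
    """Closed-form least-squares basis for fixed Miller indices.

    Solves ``min_A sum_active |A hkl_q - s_q|^2`` via the normal equations
    ``A = S M^T (M M^T)^-1`` with S = 3 x k spots and M = 3 x k indices.
    Exact interpolation when the spots are noise-free lattice points.
    """
    active = np.asarray(active, dtype=bool) & spots.mask
    if active.sum() < 3:
        raise DegenerateAssignmentError("need at least 3 active spots")
    m = hkl.hkl[active].T.astype(float)  # 3 x k
    s = spots.s[active].T  # 3 x k
    mmt = m @ m.T
    if np.linalg.matrix_rank(mmt) < 3:
        raise DegenerateAssignmentError("active Miller indices span rank < 3")
    fitted = np.linalg.solve(mmt, m @ s.T).T
    return BasisMatrix(fitted, space="reciprocal")


def residual_norms(
    basis: BasisMatrix, hkl: MillerAssignment, spots: ReciprocalSpots
) -> np.ndarray:
    """Euclidean residuals |A hkl_q - s_q| (1/angstrom); inf on padding."""
    mat = basis.matrix if isinstance(basis, BasisMatrix) else np.asarray(basis, float)
    res = np.linalg.norm(hkl.hkl @ mat.T - spots.s, axis=1)
    res = np.where(spots.mask, res, np.inf)
    return res


def _loss(res: np.ndarray, active: np.ndarray) -> float:
    return float(np.sum(res[active] ** 2))


def _fixed_point(spots, basis, active, beta, k_min):
    """Fit/trim rounds at threshold beta until the inlier set stabilises.

    Returns (basis, hkl, res, active) or None when the set collapses.
    """
    hkl = induced_miller(basis, spots)
    for _ in range(_MAX_FINAL_ROUNDS):
        try:
            basis = ls_fit_basis(spots, hkl, active)
        except DegenerateAssignmentError:
            return None
        hkl = induced_miller(basis, spots)
        res = residual_norms(basis, hkl, spots)
        new = res <= beta
        if new.sum() < k_min:
            return None
        if np.array_equal(new, active):
            return basis, hkl, res, active
        active = new
    return basis, hkl, res, active


def _grow(spots, state, beta, k_min):
    """Greedily add near-threshold excluded spots while feasibility holds."""
    basis, hkl, res, active = state
    grew = True
    while grew:
        grew = False
        for q in np.where(~active & spots.mask & (res <= 3.0 * beta))[0]:
            trial = active.copy()
            trial[q] = True
            out = _fixed_point(spots, basis, trial, beta, k_min)
            if out is not None and out[3].sum() > active.sum():
                basis, hkl, res, active = out
                grew = True
                break
    return basis, hkl, res, active


def _state_key(state):
    basis, hkl, res, active = state
    return (int(active.sum()), -float(np.sum(res[active] ** 2)))


def _local_refine(spots, basis, hkl, res, active, beta, k_min):
    """Escape local optima of the trimmed loss around a converged fit.

    Tries (a) growing the inlier set by re-admitting spots just above the
    threshold and (b) restarting the beta fixed point with each single
    inlier left out, which lets a wrongly captured outlier be displaced by
    the spots it was masking.  The best state by (cardinality, loss) wins;
    ties keep the incumbent.
    """
    best = _grow(spots, (basis, hkl, res, active), beta, k_min)
    for j in np.where(active)[0]:
        trial = active.copy()
        trial[j] = False
        if trial.sum() < 3:
            continue
        out = _fixed_point(spots, basis, trial, beta, k_min)
        if out is None:
            continue
        out = _grow(spots, out, beta, k_min)
        if _state_key(out) > _state_key(best):
            best = out
    return best


def anneal_fit(
    spots: ReciprocalSpots,
    basis0: BasisMatrix,
    params: IndexerParams,
    keep_history: bool = False,
) -> Optional[IndexingSolution]:
    """Dual-LTS fit starting from candidate basis ``basis0``.

    Each annealing round trims the active set to the spots whose residuals
    under the current fit are below the current threshold (sets are nested,
    so the trimmed loss never increases), then refits in closed form and
    re-induces Miller indices from the refitted basis.  Trimming before the
    first least-squares update (using the candidate basis's own residuals)
    keeps gross outliers from contaminating the fit on small frames.  The
    threshold starts at ``5 * beta`` and decays geometrically (factor 0.7)
    to exactly beta.  A convergence stage at beta then lets spots
    consistent with the refined fit re-enter until the set reproduces
    itself, followed by a bounded local search that can displace a wrongly
    captured outlier.  Returns None (no solution) if fewer than
    ``min_spots_kmin`` spots survive at any point or the surviving Miller
    indices become rank deficient.
    """
    beta = params.max_error_beta
    k_min = params.min_spots_kmin

    thresholds = []
    t = ANNEAL_START_FACTOR * beta
    while t > beta:
        thresholds.append(t)
        t *= ANNEAL_DECAY
    thresholds.append(beta)

    if spots.mask.sum() < k_min:
        return None

    # the candidate basis is the round-0 fit: trim on ITS residuals first,
    # so outliers cannot contaminate the first least-squares update
    basis = basis0
    hkl = induced_miller(basis, spots)
    res = residual_norms(basis, hkl, spots)
    history: list[AnnealState] = []

    def refit(active):
        nonlocal basis, hkl, res
        try:
            basis = ls_fit_basis(spots, hkl, active)
        except DegenerateAssignmentError:
            return False
        hkl = induced_miller(basis, spots)
        res = residual_norms(basis, hkl, spots)
        return True

    # annealing rounds: the active set is trimmed monotonically (nested),
    # which keeps the trimmed least-squares loss non-increasing
    active = spots.mask
    for rnd, threshold in enumerate(thresholds):
        active = active & (res < threshold if threshold > beta else res <= beta)
        if active.sum() < k_min or not refit(active):
            return None
        if keep_history:
            history.append(AnnealState(rnd, threshold, active, _loss(res, active)))

    # convergence at beta: spots consistent with the converged fit may now
    # re-enter; iterate until the trimmed set reproduces itself
    prev = None
    for _ in range(_MAX_FINAL_ROUNDS):
        active = res <= beta
        if active.sum() < k_min:
            return None
        if prev is not None and np.array_equal(active, prev):
            break
        if not refit(active):
            return None
        prev = active
    active = res <= beta
    if active.sum() < k_min:
        return None

    # the fixed point is only a local optimum of the trimmed loss; a bounded
    # local search (leave-one-out restarts + single-spot growth) recovers the
    # globally optimal subset on small contaminated frames
    basis, hkl, res, active = _local_refine(
        spots, basis, hkl, res, active, beta, k_min
    )

    accepted = bool(np.all(res[active] <= beta) and active.sum() >= k_min)
    return IndexingSolution(
        basis=basis,
        hkl=hkl,
        inlier_mask=active,
        residual_norms=res,
        num_inliers=int(active.sum()),
        accepted=accepted,
        frame_id=spots.frame_id,
        history=tuple(history),
    )
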