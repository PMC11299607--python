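"""Two-phase candidate sampling.

Phase 1 samples evenly spaced candidate lattice vectors on spheres whose
radii are the real-space cell lengths, and ranks them by how close the dot
products s.v come to integers (the Laue condition for a single vector).
Phase 2 attaches rigid copies of the ideal basis to each surviving vector
and spins them about it, producing whole-basis candidates that are ranked
by the joint three-component Laue closeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell import BasisMatrix, ReciprocalSpots, real_from_reciprocal
from .errors import ParameterError

__all__ = [
    "VectorCandidateSet",
    "BasisCandidateSet",
    "sample_sphere",
    "laue_closeness_scores",
    "rank_and_keep",
    "rotation_aligning",
    "attach_and_spin",
    "basis_scores",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class VectorCandidateSet:
    """Real-space candidate vectors for one cell axis, with Laue scores."""

    vectors: np.ndarray  # K x 3, angstrom
    axis_label: str  # "a", "b" or "c"
    scores: np.ndarray  # K


@dataclass(frozen=True)
class BasisCandidateSet:
    """Rigid rotated copies of the ideal reciprocal basis, with scores."""

    bases: np.ndarray  # T x 3 x 3, reciprocal (1/angstrom)
    parent_vector_index: np.ndarray  # T ints
    spin_angle: np.ndarray  # T, degrees
    scores: np.ndarray  # T


def sample_sphere(n: int, radius: float) -> np.ndarray:
    """``n`` quasi-uniform points on the sphere of the given radius.

    Uses the Fibonacci (golden-angle) lattice: deterministic, no randomness,
    nearest-neighbour spacing uniform to within a small constant factor.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not radius > 0:
        raise ParameterError("radius must be positive")
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = _GOLDEN_ANGLE * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # renormalise so |v| == radius to full precision
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return pts * radius


def _closeness(t: np.ndarray, kernel: str) -> np.ndarray:
    """Per-element closeness-to-integer weight in [0, 1]."""
    frac = t - np.rint(t)
    if kernel == "cosine":
        return 0.5 * (1.0 + np.cos(2.0 * np.pi * frac))
    if kernel == "threshold":
        return (np.abs(frac) < 0.25).astype(float)
    raise ParameterError(f"unknown score kernel {kernel!r}")


def laue_closeness_scores(
    spots: ReciprocalSpots, vectors: np.ndarray, kernel: str = "cosine"
) -> np.ndarray:
    """Score each real-space candidate vector v by sum_q w(s_q . v).

    w(t) = (1 + cos 2 pi t)/2 peaks at integers and vanishes at
    half-integers, so the score lies in [0, m_valid] and counts (softly) how
    many spots satisfy the one-vector Laue condition.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    s = spots.valid()
    if len(s) == 0:
        return np.zeros(len(vectors))
    t = s @ vectors.T  # m x K
    return _closeness(t, kernel).sum(axis=0)


def rank_and_keep(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k highest scores, stable (ties -> lower index first)."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    return order[: min(k, len(scores))]


def rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation R with R @ u_hat == v_hat (Rodrigues formula)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ParameterError("cannot align a zero vector")
    u = u / nu
    v = v / nv
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        # antiparallel: rotate by pi about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return _axis_angle(perp, np.pi)
    axis = np.cross(u, v)
    axis /= np.linalg.norm(axis)
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    return _axis_angle(axis, angle)


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


_AXIS_INDEX = {"a": 0, "b": 1, "c": 2}


def attach_and_spin(
    v: np.ndarray,
    b0: BasisMatrix,
    axis_label: str,
    angle_resolution: int,
) -> np.ndarray:
    """Rigid copies of B0 attached to candidate vector v, spun about it.

    The copy of B0 is rotated so that its real-space ``axis_label`` vector
    aligns with v, then spun about v; one snapshot is stored every
    ``360/angle_resolution`` degrees.  Returns an
    ``angle_resolution x 3 x 3`` stack of reciprocal bases (rotations act
    identically on the real and reciprocal bases, so each snapshot keeps the
    ideal cell's metric exactly).
    """
    if angle_resolution < 1:
        raise ParameterError("angle_resolution must be >= 1")
    v = np.asarray(v, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ParameterError("candidate vector must be nonzero")
    try:
        axis_idx = _AXIS_INDEX[axis_label]
    except KeyError:
        raise ParameterError(f"axis_label must be one of 'a','b','c', got {axis_label!r}")
    a0_real = real_from_reciprocal(b0).matrix
    r0 = rotation_aligning(a0_real[:, axis_idx], v)
    vhat = v / np.linalg.norm(v)
    angles = 2.0 * np.pi * np.arange(angle_resolution) / angle_resolution
    # batched Rodrigues about vhat
    k = np.array(
        [
            [0.0, -vhat[2], vhat[1]],
            [vhat[2], 0.0, -vhat[0]],
            [-vhat[1], vhat[0], 0.0],
        ]
    )
    k2 = k @ k
    spins = (
        np.eye(3)[None, :, :]
        + np.sin(angles)[:, None, None] * k[None, :, :]
        + (1.0 - np.cos(angles))[:, None, None] * k2[None, :, :]
    )
    return spins @ (r0 @ b0.matrix)[None, :, :]


def basis_scores(
    spots: ReciprocalSpots, bases: np.ndarray, kernel: str = "cosine"
) -> np.ndarray:
    """Joint Laue-closeness score of whole candidate bases.

    For each basis the fractional Miller coordinates ``B^-1 s_q`` are scored
    by the mean closeness of their three components, summed over valid
    spots; in [0, m_valid].  Singular bases score -inf.
    """
    bases = np.asarray(bases, dtype=float)
    if bases.ndim == 2:
        bases = bases[None]
    t = len(bases)
    scores = np.full(t, -np.inf)
    dets = np.linalg.det(bases)
    ok = np.abs(dets) > 1e-300
    if not ok.any():
        return scores
    s = spots.valid()
    if len(s) == 0:
        scores[ok] = 0.0
        return scores
    inv = np.linalg.inv(bases[ok])  # t_ok x 3 x 3
    hklf = np.einsum("tij,mj->tmi", inv, s)
    w = _closeness(hklf, kernel).mean(axis=2)  # t_ok x m
    scores[ok] = w.sum(axis=1)
    return scores
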