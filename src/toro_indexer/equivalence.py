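"""Lattice-basis equivalence up to integer unimodular changes of basis.

Two bases generate the same lattice iff they differ by an integer matrix
with determinant +-1.  Indexing can only ever recover a lattice up to such
a re-basis, so recovered solutions are compared against ground truth modulo
unimodular transforms.  By default the search covers matrices with entries
in {-1, 0, 1}, which is sufficient for near-orthogonal cells; a wider entry
range can be requested for strongly sheared cells.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .cell import BasisMatrix

__all__ = ["unimodular_matrices", "basis_mismatch", "bases_equivalent", "metrics_equivalent"]


@lru_cache(maxsize=4)
def unimodular_matrices(entry_range: int = 1) -> np.ndarray:
    """All 3x3 integer matrices with entries in [-entry_range, entry_range]
    and determinant +-1, as an N x 3 x 3 array."""
    vals = np.arange(-entry_range, entry_range + 1)
    grids = np.meshgrid(*([vals] * 9), indexing="ij")
    flat = np.stack([g.ravel() for g in grids], axis=1).reshape(-1, 3, 3)
    dets = np.linalg.det(flat.astype(float))
    keep = np.abs(np.abs(dets) - 1.0) < 1e-9
    out = flat[keep].astype(np.int64)
    out.setflags(write=False)
    return out


def _mat(b) -> np.ndarray:
    return b.matrix if isinstance(b, BasisMatrix) else np.asarray(b, dtype=float)


def basis_mismatch(fitted, truth, entry_range: int = 1) -> float:
    """min over unimodular U of ||fitted @ U - truth||_F / ||truth||_F.

    Both bases must be expressed in the same (lab) frame; no rotation is
    factored out.
    """
    f = _mat(fitted)
    t = _mat(truth)
    us = unimodular_matrices(entry_range)
    diffs = f[None, :, :] @ us.astype(float) - t[None, :, :]
    errs = np.linalg.norm(diffs, axis=(1, 2)) / np.linalg.norm(t)
    return float(errs.min())


def bases_equivalent(fitted, truth, tol: float = 1e-3, entry_range: int = 1) -> bool:
    """Whether two same-frame bases generate the same lattice within tol."""
    return basis_mismatch(fitted, truth, entry_range) <= tol


def metrics_equivalent(g_fitted, g_truth, tol: float = 1e-4, entry_range: int = 1) -> bool:
    """Whether two Gram matrices agree under some unimodular re-basis.

    Orientation-free: compares A^T A against U^T G U over unimodular U.
    """
    gf = np.asarray(g_fitted, dtype=float)
    gt = np.asarray(g_truth, dtype=float)
    us = unimodular_matrices(entry_range).astype(float)
    cand = np.einsum("nji,jk,nkl->nil", us, gf, us)
    errs = np.linalg.norm(cand - gt[None], axis=(1, 2)) / np.linalg.norm(gt)
    return bool(errs.min() <= tol)
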