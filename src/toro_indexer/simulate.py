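"""Synthetic diffraction frames with full ground truth.

A frame is generated by rotating the ideal reciprocal basis by a uniform
(Haar) random rotation, enumerating the reciprocal lattice points that fall
inside a thin slab around the Ewald sphere (the stand-in for mosaicity /
bandwidth making reflections observable), sampling the requested number of
them, adding isotropic Gaussian positional noise, and replacing a fraction
with uniform outliers drawn from the same Ewald slab (geometrically
plausible false peaks).  Orientation, Miller indices, inlier labels and
per-crystal ids are all recorded, so the simulator doubles as the ground
-truth oracle for the fitting and selection tests.

Frames can optionally be projected onto the detector; in that case the
spots are first snapped onto the Ewald sphere (a detector peak determines
the scattered-ray direction, hence a reciprocal vector exactly on the
sphere), making the detector -> reciprocal round trip exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .cell import (
    BasisMatrix,
    GeometryConfig,
    PeakList,
    ReciprocalSpots,
    UnitCell,
    reciprocal_basis_from_cell,
)
from .errors import SimulationError
from .fitting import MillerAssignment

__all__ = ["SimulatedFrame", "random_rotation", "simulate_frame"]

DEFAULT_SLAB_WIDTH = 0.003  # 1/angstrom
DEFAULT_S_MAX = 0.35  # 1/angstrom; ~150-1000 reachable points for 40-80 A cells


@dataclass(frozen=True)
class SimulatedFrame:
    """A synthetic frame plus every piece of ground truth about it."""

    spots: ReciprocalSpots
    true_bases: tuple  # tuple[BasisMatrix, ...], one per crystal
    true_hkl: MillerAssignment  # (0,0,0) for outliers
    inlier_labels: np.ndarray  # bools
    crystal_id: np.ndarray  # per-spot int, -1 for outliers
    seed: int
    n_reachable: tuple  # reachable lattice points per crystal
    peaks: Optional[PeakList] = None  # detector projection, if requested

    @property
    def true_basis(self) -> BasisMatrix:
        return self.true_bases[0]


def random_rotation(seed) -> np.ndarray:
    """A proper rotation drawn uniformly (Haar); deterministic per seed.

    ``seed`` may be an int or a numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return Rotation.random(rng=rng).as_matrix()


def _ewald_distance(s: np.ndarray, wavelength: float) -> np.ndarray:
    centre = np.array([0.0, 0.0, -1.0 / wavelength])
    return np.abs(np.linalg.norm(s - centre, axis=-1) - 1.0 / wavelength)


def _reachable_points(basis: np.ndarray, wavelength: float, s_max: float, slab: float):
    """All lattice points with |s| <= s_max inside the Ewald slab."""
    real = np.linalg.inv(basis).T
    max_idx = np.floor(s_max * np.linalg.norm(real, axis=0)).astype(int) + 1
    axes = [np.arange(-m, m + 1) for m in max_idx]
    hkl = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    s = hkl @ basis.T
    ok = (np.linalg.norm(s, axis=1) <= s_max) & (_ewald_distance(s, wavelength) <= slab)
    return hkl[ok], s[ok]


def _sample_outliers(rng, n, wavelength, s_max, slab):
    """Uniform points in the Ewald-slab shell with |s| <= s_max."""
    centre = np.array([0.0, 0.0, -1.0 / wavelength])
    out = np.empty((0, 3))
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        radii = 1.0 / wavelength + rng.uniform(-slab, slab, size=m)
        s = centre + radii[:, None] * u
        s = s[np.linalg.norm(s, axis=1) <= s_max]
        out = np.vstack([out, s])
    return out[:n]


def _project_to_detector(s: np.ndarray, geom: GeometryConfig):
    """Snap spots onto the Ewald sphere and project onto the detector plane.

    Returns (snapped spots, detector mm positions).  Requires forward
    scattering (ray z-component > 0), which holds for |s| < sqrt(2)/lambda.
    """
    zhat = np.array([0.0, 0.0, 1.0])
    d = s + zhat / geom.wavelength
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise SimulationError("spot maps to a degenerate (backward) ray")
    dhat = d / norms[:, None]
    if np.any(dhat[:, 2] <= 0):
        raise SimulationError(
            "spot scatters away from the detector; reduce s_max below sqrt(2)/wavelength"
        )
    snapped = dhat / geom.wavelength - zhat / geom.wavelength
    scale = geom.distance / dhat[:, 2]
    xy = dhat[:, :2] * scale[:, None] + np.asarray(geom.beam_center)
    return snapped, xy


def simulate_frame(
    cell: UnitCell,
    geom: GeometryConfig,
    n_spots: int = 40,
    noise_sigma: float = 0.0,
    outlier_fraction: float = 0.0,
    n_crystals: int = 1,
    slab_width: float = DEFAULT_SLAB_WIDTH,
    seed: int = 0,
    s_max: float = DEFAULT_S_MAX,
    project_to_detector: bool = False,
    frame_id: str = "",
) -> SimulatedFrame:
    """Generate one frame with known orientation(s) and labels.

    ``n_spots`` counts all spots including outliers; with several crystals
    the non-outlier spots are split as evenly as possible between them,
    each with its own uniformly random orientation.
    """
    if n_spots < 1:
        raise SimulationError("n_spots must be >= 1")
    if not 0 <= outlier_fraction < 1:
        raise SimulationError("outlier_fraction must lie in [0, 1)")
    if n_crystals < 1:
        raise SimulationError("n_crystals must be >= 1")
    if slab_width <= 0 or s_max <= 0 or noise_sigma < 0:
        raise SimulationError("slab_width and s_max must be positive, noise_sigma >= 0")

    rng = np.random.default_rng(seed)
    b0 = reciprocal_basis_from_cell(cell).matrix

    n_outliers = int(round(outlier_fraction * n_spots))
    n_lattice = n_spots - n_outliers
    per_crystal = [
        n_lattice // n_crystals + (1 if i < n_lattice % n_crystals else 0)
        for i in range(n_crystals)
    ]

    bases = []
    all_s, all_hkl, all_cid = [], [], []
    reachable_counts = []
    for ci, n_c in enumerate(per_crystal):
        rot = random_rotation(rng)
        basis = rot @ b0
        bases.append(BasisMatrix(basis, space="reciprocal"))
        hkl, s = _reachable_points(basis, geom.wavelength, s_max, slab_width)
        reachable_counts.append(len(hkl))
        if len(hkl) < n_c:
            raise SimulationError(
                f"crystal {ci}: only {len(hkl)} reachable lattice points "
                f"for {n_c} requested spots; increase s_max or slab_width"
            )
        pick = rng.choice(len(hkl), size=n_c, replace=False)
        all_s.append(s[pick])
        all_hkl.append(hkl[pick])
        all_cid.append(np.full(n_c, ci))

    s = np.vstack(all_s) if all_s else np.empty((0, 3))
    hkl = np.vstack(all_hkl) if all_hkl else np.empty((0, 3), dtype=int)
    cid = np.concatenate(all_cid) if all_cid else np.empty(0, dtype=int)
    if noise_sigma > 0 and len(s):
        s = s + rng.normal(scale=noise_sigma, size=s.shape)

    if n_outliers:
        s_out = _sample_outliers(rng, n_outliers, geom.wavelength, s_max, slab_width)
        s = np.vstack([s, s_out])
        hkl = np.vstack([hkl, np.zeros((n_outliers, 3), dtype=int)])
        cid = np.concatenate([cid, np.full(n_outliers, -1)])

    labels = cid >= 0
    perm = rng.permutation(len(s))
    s, hkl, cid, labels = s[perm], hkl[perm], cid[perm], labels[perm]

    peaks = None
    if project_to_detector:
        s, xy = _project_to_detector(s, geom)
        peaks = PeakList(xy, frame_id=frame_id, unit="mm")

    return SimulatedFrame(
        spots=ReciprocalSpots(s, np.ones(len(s), dtype=bool), frame_id),
        true_bases=tuple(bases),
        true_hkl=MillerAssignment(hkl),
        inlier_labels=labels,
        crystal_id=cid,
        seed=seed if isinstance(seed, int) else -1,
        n_reachable=tuple(reachable_counts),
        peaks=peaks,
    )
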