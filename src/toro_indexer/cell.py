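"""Unit cells, lattice bases and the detector -> reciprocal-space mapping.

Conventions used throughout the package
---------------------------------------
* Lab frame: right-handed, X-ray beam along +z, flat detector plane
  perpendicular to z at ``z = distance``.  Detector x, y increase with the
  fast/slow pixel indices; pixel coordinates are 0-based at pixel centres and
  convert to mm as ``mm = pixel * pixel_size``.
* Internal units are angstrom (real space) and inverse angstrom (reciprocal
  space) everywhere; nm^-1 appears only in the stream-style writer.
* The canonical orientation of a cell's basis puts the real-space a vector
  along +x and b in the xy-plane, right-handed.

A reciprocal spot is the scattering vector ``s = (1/lambda) * (p/|p| - z_hat)``
of a Bragg peak observed at lab position ``p`` on the detector; all such
vectors lie on the Ewald sphere of radius ``1/lambda`` centred at
``-z_hat/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidCellError, InvalidGeometryError, SingularBasisError

__all__ = [
    "LATTICE_TYPES",
    "CENTERINGS",
    "UnitCell",
    "BasisMatrix",
    "GeometryConfig",
    "PeakList",
    "ReciprocalSpots",
    "reciprocal_basis_from_cell",
    "real_from_reciprocal",
    "cell_from_basis",
    "map_peaks_to_reciprocal",
]

LATTICE_TYPES = (
    "triclinic",
    "monoclinic",
    "orthorhombic",
    "tetragonal",
    "hexagonal",
    "rhombohedral",
    "cubic",
)
CENTERINGS = ("P", "A", "B", "C", "I", "F", "H", "R")

# tolerance used when checking lattice_type constraints such as a == b
_LATTICE_REL_TOL = 1e-4
_LATTICE_ANG_TOL = 1e-2  # degrees


def _check_lattice_constraints(cell: "UnitCell") -> None:
    a, b, c = cell.a, cell.b, cell.c
    al, be, ga = cell.alpha, cell.beta, cell.gamma

    def leq(x, y):
        return abs(x - y) <= _LATTICE_REL_TOL * max(abs(x), abs(y))

    def aeq(x, y):
        return abs(x - y) <= _LATTICE_ANG_TOL

    lt = cell.lattice_type
    ok = True
    if lt == "cubic":
        ok = leq(a, b) and leq(b, c) and all(aeq(x, 90.0) for x in (al, be, ga))
    elif lt == "tetragonal":
        ok = leq(a, b) and all(aeq(x, 90.0) for x in (al, be, ga))
    elif lt == "orthorhombic":
        ok = all(aeq(x, 90.0) for x in (al, be, ga))
    elif lt == "hexagonal":
        ok = leq(a, b) and aeq(al, 90.0) and aeq(be, 90.0) and aeq(ga, 120.0)
    elif lt == "rhombohedral":
        ok = leq(a, b) and leq(b, c) and aeq(al, be) and aeq(be, ga)
    elif lt == "monoclinic":
        # unique axis b convention: alpha = gamma = 90
        ok = aeq(al, 90.0) and aeq(ga, 90.0)
    if not ok:
        raise InvalidCellError(
            f"cell parameters {a, b, c, al, be, ga} violate "
            f"lattice_type={lt!r} constraints"
        )


@dataclass(frozen=True)
class UnitCell:
    """The six cell parameters (lengths in angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    lattice_type: str = "triclinic"
    centering: str = "P"

    def __post_init__(self) -> None:
        if not all(x > 0 for x in (self.a, self.b, self.c)):
            raise InvalidCellError("cell lengths must be positive")
        if not all(0.0 < x < 180.0 for x in (self.alpha, self.beta, self.gamma)):
            raise InvalidCellError("cell angles must lie in (0, 180) degrees")
        if self.lattice_type not in LATTICE_TYPES:
            raise InvalidCellError(f"unknown lattice_type {self.lattice_type!r}")
        if self.centering not in CENTERINGS:
            raise InvalidCellError(f"unknown centering {self.centering!r}")
        # positive-definite metric <=> positive volume term
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        vterm = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if vterm <= 0.0:
            raise InvalidCellError("angles give a non-positive-definite metric tensor")
        _check_lattice_constraints(self)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c])

    @property
    def angles(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])

    def metric_tensor(self) -> np.ndarray:
        """Real-space metric G with G_ij = a_i . a_j (angstrom^2)."""
        a, b, c = self.a, self.b, self.c
        ca, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return np.array(
            [
                [a * a, a * b * cg, a * c * cb],
                [a * b * cg, b * b, b * c * ca],
                [a * c * cb, b * c * ca, c * c],
            ]
        )

    def volume(self) -> float:
        """Cell volume in angstrom^3."""
        return float(np.sqrt(np.linalg.det(self.metric_tensor())))


def _frozen_array(x, shape=None, dtype=float) -> np.ndarray:
    arr = np.asarray(x, dtype=dtype)
    if shape is not None and arr.shape != shape:
        raise ValueError(f"expected shape {shape}, got {arr.shape}")
    arr = arr.copy()
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class BasisMatrix:
    """3x3 matrix whose COLUMNS are lattice basis vectors.

    ``space`` is "reciprocal" (columns a*, b*, c* in 1/angstrom) or "real"
    (columns a, b, c in angstrom).  A reciprocal basis B and its real dual D
    satisfy ``D.T @ B == I``.
    """

    matrix: np.ndarray
    space: str = "reciprocal"

    def __post_init__(self) -> None:
        if self.space not in ("reciprocal", "real"):
            raise ValueError(f"space must be 'reciprocal' or 'real', got {self.space!r}")
        object.__setattr__(self, "matrix", _frozen_array(self.matrix, (3, 3)))

    @property
    def columns(self) -> np.ndarray:
        return self.matrix.T  # convenience: columns[i] is the i-th basis vector

    def det(self) -> float:
        return float(np.linalg.det(self.matrix))


@dataclass(frozen=True)
class GeometryConfig:
    """Single flat-panel detector geometry; the beam travels along +z."""

    wavelength: float  # angstrom
    distance: float  # mm, sample to detector along the beam
    beam_center: tuple[float, float] = (0.0, 0.0)  # mm on the detector
    pixel_size: float = 0.1  # mm / pixel

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise InvalidGeometryError("wavelength must be positive")
        if self.distance <= 0:
            raise InvalidGeometryError("distance must be positive")
        if self.pixel_size <= 0:
            raise InvalidGeometryError("pixel_size must be positive")


@dataclass(frozen=True)
class PeakList:
    """Detector-space peak positions for one frame (unit: "mm" or "pixel")."""

    positions: np.ndarray  # n x 2
    frame_id: str = ""
    unit: str = "mm"
    intensities: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.size == 0:
            pos = pos.reshape(0, 2)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an n x 2 array")
        if not np.all(np.isfinite(pos)):
            raise ValueError("peak coordinates must be finite")
        if self.unit not in ("mm", "pixel"):
            raise ValueError(f"unit must be 'mm' or 'pixel', got {self.unit!r}")
        object.__setattr__(self, "positions", _frozen_array(pos))
        if self.intensities is not None:
            inten = _frozen_array(self.intensities, (len(pos),))
            if np.any(inten < 0):
                raise ValueError("intensities must be non-negative")
            object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ReciprocalSpots:
    """A frame's reciprocal spots (1/angstrom) with a padding-aware mask."""

    s: np.ndarray  # m x 3
    mask: Optional[np.ndarray] = None  # m bools, False = padding
    frame_id: str = ""

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.s, dtype=float))
        if s.size == 0:
            s = s.reshape(0, 3)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError("s must be an m x 3 array")
        mask = self.mask
        if mask is None:
            mask = np.ones(len(s), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(s),):
            raise ValueError("mask length must match number of spots")
        object.__setattr__(self, "s", _frozen_array(s))
        object.__setattr__(self, "mask", _frozen_array(mask, dtype=bool))

    def __len__(self) -> int:
        return len(self.s)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid(self) -> np.ndarray:
        """The mask-true rows only."""
        return self.s[self.mask]


def reciprocal_basis_from_cell(cell: UnitCell) -> BasisMatrix:
    """Ideal reciprocal basis B0 of ``cell`` in the canonical orientation.

    The real basis is built with a along +x and b in the xy-plane
    (right-handed); B0 is its dual, so ``A0.T @ B0 == I``.
    """
    a, b, c = cell.a, cell.b, cell.c
    ca, cb, cg = (np.cos(np.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = np.sin(np.radians(cell.gamma))
    # canonical real basis (columns a, b, c)
    cz_sq = 1.0 - cb * cb - ((ca - cb * cg) / sg) ** 2
    if cz_sq <= 0:
        raise InvalidCellError("angles give a non-positive-definite metric tensor")
    areal = np.array(
        [
            [a, b * cg, c * cb],
            [0.0, b * sg, c * (ca - cb * cg) / sg],
            [0.0, 0.0, c * np.sqrt(cz_sq)],
        ]
    )
    recip = np.linalg.inv(areal).T
    return BasisMatrix(recip, space="reciprocal")


def real_from_reciprocal(basis: BasisMatrix) -> BasisMatrix:
    """Dual of a basis: D with ``D.T @ B == I`` (works in either direction)."""
    mat = basis.matrix
    det = np.linalg.det(mat)
    if abs(det) < 1e-300 or not np.isfinite(det):
        raise SingularBasisError("basis matrix is singular")
    dual = np.linalg.inv(mat).T
    other = "real" if basis.space == "reciprocal" else "reciprocal"
    return BasisMatrix(dual, space=other)


def cell_from_basis(basis: BasisMatrix) -> UnitCell:
    """Cell parameters (lengths/angles) of the REAL lattice behind ``basis``."""
    real = basis if basis.space == "real" else real_from_reciprocal(basis)
    cols = real.matrix.T
    lengths = np.linalg.norm(cols, axis=1)
    if np.any(lengths <= 0):
        raise SingularBasisError("zero-length basis vector")

    def ang(i, j):
        cosv = np.dot(cols[i], cols[j]) / (lengths[i] * lengths[j])
        return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))

    return UnitCell(
        float(lengths[0]), float(lengths[1]), float(lengths[2]),
        ang(1, 2), ang(0, 2), ang(0, 1),
    )


def map_peaks_to_reciprocal(peaks: PeakList, geom: GeometryConfig) -> ReciprocalSpots:
    """Map detector peak positions onto the Ewald sphere.

    A peak at detector position (x, y) sits at lab position
    ``p = (x - x0, y - y0, distance)`` (mm); its reciprocal spot is
    ``s = (1/lambda) * (p/|p| - z_hat)``, which lies on the sphere of radius
    ``1/lambda`` centred at ``-z_hat/lambda``.
    """
    pos = np.asarray(peaks.positions, dtype=float)
    if peaks.unit == "pixel":
        pos = pos * geom.pixel_size
    xy = pos - np.asarray(geom.beam_center)
    p = np.column_stack([xy, np.full(len(xy), geom.distance)])
    norms = np.linalg.norm(p, axis=1)
    if np.any(norms == 0):
        raise InvalidGeometryError("peak coincides with the sample position")
    direction = p / norms[:, None]
    s = (direction - np.array([0.0, 0.0, 1.0])) / geom.wavelength
    return ReciprocalSpots(s=s, mask=np.ones(len(s), dtype=bool), frame_id=peaks.frame_id)
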