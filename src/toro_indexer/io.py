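"""Readers and writers for cell files, geometry configs, peak lists and results.

Cell files follow the CrystFEL key = value dialect (lengths with an "A"
suffix, angles with "deg").  Geometry is a deliberately minimal flat
key = value file for a single flat panel.  Peak lists are CSV (columns
``frame_id, x, y[, intensity]`` in detector space or ``frame_id, sx, sy,
sz`` pre-mapped, 1/angstrom) or HDF5 with equivalently named datasets.
Results are written as JSON (canonical, loss-free) or as a CrystFEL
stream-like text block (nm^-1, best-effort interoperability).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import List, Sequence, Union

import h5py
import numpy as np
import pandas as pd

from .cell import (
    BasisMatrix,
    GeometryConfig,
    PeakList,
    ReciprocalSpots,
    UnitCell,
    cell_from_basis,
)
from .errors import CellFileError
from .fitting import IndexingSolution, MillerAssignment

__all__ = [
    "read_cell_file",
    "read_geometry_file",
    "read_peaks",
    "write_solutions",
    "read_solutions_json",
]

_CELL_MANDATORY = ("a", "b", "c", "al", "be", "ga")
_CELL_KNOWN = set(_CELL_MANDATORY) | {"lattice_type", "centering", "unique_axis"}


def _parse_kv_lines(path):
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split(";")[0].split("#")[0].strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        yield lineno, key.strip(), value.strip()


def read_cell_file(path) -> UnitCell:
    """Parse a CrystFEL-style unit-cell file."""
    values = {}
    for lineno, key, value in _parse_kv_lines(path):
        if key not in _CELL_KNOWN:
            warnings.warn(f"{path}:{lineno}: ignoring unknown cell key {key!r}")
            continue
        values[key] = (lineno, value)
    missing = [k for k in _CELL_MANDATORY if k not in values]
    if missing:
        raise CellFileError(f"{path}: missing mandatory cell keys: {', '.join(missing)}")

    def number(key, suffix):
        lineno, value = values[key]
        token = value.split()
        if len(token) == 2 and token[1] != suffix:
            raise CellFileError(
                f"{path}:{lineno}: expected unit {suffix!r} for {key}, got {token[1]!r}"
            )
        try:
            return float(token[0])
        except (ValueError, IndexError):
            raise CellFileError(f"{path}:{lineno}: malformed value for {key}: {value!r}")

    return UnitCell(
        a=number("a", "A"),
        b=number("b", "A"),
        c=number("c", "A"),
        alpha=number("al", "deg"),
        beta=number("be", "deg"),
        gamma=number("ga", "deg"),
        lattice_type=values.get("lattice_type", (0, "triclinic"))[1],
        centering=values.get("centering", (0, "P"))[1],
    )


def write_cell_file(cell: UnitCell, path) -> None:
    Path(path).write_text(
        "CrystFEL unit cell file version 1.0\n\n"
        f"lattice_type = {cell.lattice_type}\n"
        f"centering = {cell.centering}\n"
        f"a = {cell.a:.6f} A\n"
        f"b = {cell.b:.6f} A\n"
        f"c = {cell.c:.6f} A\n"
        f"al = {cell.alpha:.6f} deg\n"
        f"be = {cell.beta:.6f} deg\n"
        f"ga = {cell.gamma:.6f} deg\n"
    )


_GEOM_KEYS = {
    "wavelength_A": "wavelength",
    "distance_mm": "distance",
    "beam_center_x_mm": "bcx",
    "beam_center_y_mm": "bcy",
    "pixel_size_mm": "pixel_size",
}


def read_geometry_file(path) -> GeometryConfig:
    """Parse the flat single-panel geometry format."""
    values = {}
    for lineno, key, value in _parse_kv_lines(path):
        if key not in _GEOM_KEYS:
            warnings.warn(f"{path}:{lineno}: ignoring unknown geometry key {key!r}")
            continue
        try:
            values[_GEOM_KEYS[key]] = float(value.split()[0])
        except ValueError:
            raise CellFileError(f"{path}:{lineno}: malformed value {value!r}")
    missing = [k for k, v in _GEOM_KEYS.items() if v not in values and v not in ("bcx", "bcy")]
    if missing:
        raise CellFileError(f"{path}: missing mandatory geometry keys: {', '.join(missing)}")
    return GeometryConfig(
        wavelength=values["wavelength"],
        distance=values["distance"],
        beam_center=(values.get("bcx", 0.0), values.get("bcy", 0.0)),
        pixel_size=values["pixel_size"],
    )


def write_geometry_file(geom: GeometryConfig, path) -> None:
    Path(path).write_text(
        f"wavelength_A = {geom.wavelength}\n"
        f"distance_mm = {geom.distance}\n"
        f"beam_center_x_mm = {geom.beam_center[0]}\n"
        f"beam_center_y_mm = {geom.beam_center[1]}\n"
        f"pixel_size_mm = {geom.pixel_size}\n"
    )


def _frames_from_table(df: pd.DataFrame, space: str, unit: str):
    detector_cols = {"x", "y"}
    reciprocal_cols = {"sx", "sy", "sz"}
    cols = set(df.columns)
    if space == "detector":
        if not detector_cols <= cols:
            raise CellFileError("detector-space peaks need columns frame_id, x, y")
        coord_cols = ["x", "y"]
    elif space == "reciprocal":
        if not reciprocal_cols <= cols:
            raise CellFileError("reciprocal-space peaks need columns frame_id, sx, sy, sz")
        coord_cols = ["sx", "sy", "sz"]
    else:
        raise CellFileError(f"space must be 'detector' or 'reciprocal', got {space!r}")
    if "frame_id" not in cols:
        raise CellFileError("peak tables need a frame_id column")

    n_bad = int(df[coord_cols].isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} peak row(s) with NaN coordinates")
        df = df.dropna(subset=coord_cols)

    out = []
    for fid, grp in df.groupby("frame_id", sort=False):
        fid = str(fid)
        if space == "detector":
            inten = grp["intensity"].to_numpy() if "intensity" in cols else None
            out.append(
                PeakList(grp[coord_cols].to_numpy(float), frame_id=fid, unit=unit,
                         intensities=inten)
            )
        else:
            out.append(ReciprocalSpots(grp[coord_cols].to_numpy(float), frame_id=fid))
    return out


def read_peaks(
    path, space: str = "detector", unit: str = "mm"
) -> Union[List[PeakList], List[ReciprocalSpots]]:
    """Read a CSV or HDF5 peak list, grouped by frame_id in file order.

    ``space='detector'`` yields :class:`PeakList` objects (coordinates in
    ``unit``, "mm" or "pixel"); ``space='reciprocal'`` yields
    :class:`ReciprocalSpots` (1/angstrom).  Rows with NaN coordinates are
    dropped with a warning stating the count.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            data = {}
            for name in ("frame_id", "x", "y", "sx", "sy", "sz", "intensity"):
                if name in f:
                    arr = f[name][()]
                    if arr.dtype.kind in ("S", "O"):
                        arr = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                        for v in arr])
                    data[name] = arr
            df = pd.DataFrame(data)
    else:
        df = pd.read_csv(path)
    return _frames_from_table(df, space, unit)


def _solution_record(sol: IndexingSolution) -> dict:
    basis = sol.basis.matrix
    fitted_cell = cell_from_basis(sol.basis)
    return {
        "frame_id": sol.frame_id,
        "reciprocal_basis_invA": basis.T.tolist(),  # rows a*, b*, c*
        "reciprocal_basis_invnm": (basis.T * 10.0).tolist(),
        "cell": {
            "a": fitted_cell.a, "b": fitted_cell.b, "c": fitted_cell.c,
            "alpha": fitted_cell.alpha, "beta": fitted_cell.beta,
            "gamma": fitted_cell.gamma,
        },
        "num_inliers": sol.num_inliers,
        "penalty": sol.penalty,
        "accepted": sol.accepted,
        "hkl": sol.hkl.hkl.tolist(),
        "inlier_flags": sol.inlier_mask.astype(bool).tolist(),
        "residual_norms_invA": [
            None if not np.isfinite(r) else r for r in sol.residual_norms
        ],
    }


def _record_solution(rec: dict) -> IndexingSolution:
    res = np.array(
        [np.inf if r is None else r for r in rec["residual_norms_invA"]], dtype=float
    )
    return IndexingSolution(
        basis=BasisMatrix(np.asarray(rec["reciprocal_basis_invA"]).T, "reciprocal"),
        hkl=MillerAssignment(np.asarray(rec["hkl"], dtype=int)),
        inlier_mask=np.asarray(rec["inlier_flags"], dtype=bool),
        residual_norms=res,
        num_inliers=int(rec["num_inliers"]),
        penalty=float(rec["penalty"]),
        accepted=bool(rec["accepted"]),
        frame_id=str(rec["frame_id"]),
    )


def write_solutions(
    results: Sequence[tuple[str, Sequence[IndexingSolution]]],
    path,
    format: str = "json",
) -> None:
    """Write per-frame indexing results.

    ``results`` is a sequence of (frame_id, solutions) pairs.  "json" is the
    canonical loss-free format; "stream" emits a CrystFEL-stream-like text
    block with astar/bstar/cstar rows in nm^-1.
    """
    path = Path(path)
    if format == "json":
        payload = [
            {"frame_id": fid, "solutions": [_solution_record(s) for s in sols]}
            for fid, sols in results
        ]
        path.write_text(json.dumps(payload, indent=1))
    elif format == "stream":
        lines = []
        for fid, sols in results:
            lines.append("----- Begin chunk -----")
            lines.append(f"Image filename: {fid}")
            lines.append(f"num_crystals = {len(sols)}")
            for sol in sols:
                cellp = cell_from_basis(sol.basis)
                cols = sol.basis.matrix.T * 10.0  # rows a*,b*,c* in nm^-1
                lines.append("--- Begin crystal")
                lines.append(
                    "Cell parameters "
                    f"{cellp.a / 10:.5f} {cellp.b / 10:.5f} {cellp.c / 10:.5f} nm, "
                    f"{cellp.alpha:.5f} {cellp.beta:.5f} {cellp.gamma:.5f} deg"
                )
                for name, row in zip(("astar", "bstar", "cstar"), cols):
                    lines.append(
                        f"{name} = {row[0]:.7f} {row[1]:.7f} {row[2]:.7f} nm^-1"
                    )
                lines.append(f"num_reflections = {sol.num_inliers}")
                lines.append("--- End crystal")
            lines.append("----- End chunk -----")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"format must be 'json' or 'stream', got {format!r}")


def read_solutions_json(path) -> List[tuple[str, List[IndexingSolution]]]:
    """Inverse of :func:`write_solutions` for the JSON format."""
    payload = json.loads(Path(path).read_text())
    return [
        (rec["frame_id"], [_record_solution(r) for r in rec["solutions"]])
        for rec in payload
    ]
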