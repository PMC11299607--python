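"""Indexer hyperparameters and the published speed/quality presets."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ParameterError

__all__ = ["IndexerParams", "PRESETS"]


@dataclass(frozen=True)
class IndexerParams:
    """All tunables of the indexing pipeline.

    lattice_size
        Number of evenly spaced candidate vectors sampled on each per-axis
        sphere (Fibonacci lattice points).
    angle_resolution
        Spin snapshots per full 360 degree turn when attaching basis copies
        to a candidate vector.
    num_top_solutions
        Candidate bases passed on to the robust fitting stage.
    num_top_vectors
        Candidate vectors kept per axis after Laue-closeness ranking.
    max_error_beta
        Maximum allowed residual |A~ hkl - s| (1/angstrom) for an inlier;
        the bound beta that defines an acceptable solution.
    min_spots_kmin
        Minimum number of inliers for a valid solution (k_min); below this
        the fit reports no solution.
    max_spots
        Fixed per-frame spot count for batching; frames are pruned to the
        lowest-resolution spots or zero-padded to this size.
    max_lattices
        Maximum number of (near-disjoint) lattices reported per frame.
    length_tol, angle_tol
        Cell-shape acceptance window: relative length deviation and absolute
        angle deviation (degrees) of a fitted cell from the ideal cell.
    score_kernel
        "cosine" (smooth, default) or "threshold" (hard count of products
        within 0.25 of an integer) for the Laue-closeness ranking.
    seed
        Governs only synthetic-data generation; the pipeline itself is
        deterministic.
    """

    lattice_size: int = 50000
    angle_resolution: int = 150
    num_top_solutions: int = 400
    num_top_vectors: int = 64
    max_error_beta: float = 0.002
    min_spots_kmin: int = 10
    max_spots: int = 80
    max_lattices: int = 2
    length_tol: float = 0.05
    angle_tol: float = 3.0
    score_kernel: str = "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "lattice_size",
            "angle_resolution",
            "num_top_solutions",
            "num_top_vectors",
            "min_spots_kmin",
            "max_spots",
            "max_lattices",
        ):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if not self.max_error_beta > 0:
            raise ParameterError("max_error_beta must be positive")
        if not 0 < self.length_tol < 1:
            raise ParameterError("length_tol must lie in (0, 1)")
        if not self.angle_tol > 0:
            raise ParameterError("angle_tol must be positive")
        if self.score_kernel not in ("cosine", "threshold"):
            raise ParameterError("score_kernel must be 'cosine' or 'threshold'")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "IndexerParams":
        """The published presets: "full" (quality) or "rt" (real time)."""
        try:
            base = PRESETS[name]
        except KeyError:
            raise ParameterError(
                f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
            ) from None
        return replace(base, **overrides) if overrides else base


PRESETS = {
    "full": IndexerParams(
        lattice_size=50000, angle_resolution=150, num_top_solutions=400
    ),
    "rt": IndexerParams(
        lattice_size=10000, angle_resolution=100, num_top_solutions=25
    ),
}
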