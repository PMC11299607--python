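import numpy as np
import pytest

from toro_indexer import (
    GeometryConfig,
    IndexerParams,
    UnitCell,
    simulate_frame,
)

# moderately anisotropic orthorhombic cell: every axis distinguishable,
# lattice spacings comfortably resolvable at the default noise scale
STD_CELL = UnitCell(40.0, 45.0, 50.0, 90.0, 90.0, 90.0, "orthorhombic", "P")
STD_GEOM = GeometryConfig(wavelength=1.0, distance=100.0, beam_center=(0.0, 0.0),
                          pixel_size=0.1)


@pytest.fixture(scope="session")
def cell():
    return STD_CELL


@pytest.fixture(scope="session")
def geom():
    return STD_GEOM


@pytest.fixture(scope="session")
def triclinic_cell():
    return UnitCell(10.0, 12.0, 15.0, 80.0, 95.0, 100.0)


@pytest.fixture(scope="session")
def desk_params():
    """RT-like settings scaled down for quick unit tests."""
    return IndexerParams.from_preset("rt", lattice_size=2000)


@pytest.fixture(scope="session")
def noisy_frame(cell, geom, desk_params):
    beta = desk_params.max_error_beta
    return simulate_frame(
        cell, geom, n_spots=40, noise_sigma=0.25 * beta,
        outlier_fraction=0.2, seed=42,
    )


def random_basis(rng, scale=0.05):
    """A random well-conditioned 3x3 reciprocal basis."""
    while True:
        m = rng.uniform(-scale, scale, size=(3, 3)) + scale * np.eye(3)
        if abs(np.linalg.det(m)) > 1e-5 * scale**3:
            return m
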