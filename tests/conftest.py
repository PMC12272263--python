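import numpy as np
import pytest

from tmsnet import (
    RunConfig,
    amplitude_for_correlation,
    human_profile,
    macaque_profile,
    make_folded_sheet,
    make_parcellation,
)
from tmsnet.surface import SurfaceMesh, _vertex_normals


def lattice_mesh(nx: int, ny: int, spacing: float = 1.0,
                 z: np.ndarray | None = None) -> SurfaceMesh:
    """Small hand-built flat (or given-height) lattice for unit tests."""
    x = np.arange(nx) * spacing
    y = np.arange(ny) * spacing
    xx, yy = np.meshgrid(x, y)
    zz = np.zeros_like(xx) if z is None else np.asarray(z, float)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v00 = (iy * nx + ix).ravel()
    faces = np.concatenate(
        [
            np.column_stack([v00, v00 + 1, v00 + nx + 1]),
            np.column_stack([v00, v00 + nx + 1, v00 + nx]),
        ]
    )
    return SurfaceMesh(vertices, faces, _vertex_normals(vertices, faces),
                       grid_shape=(ny, nx))


@pytest.fixture(scope="session")
def human_mesh():
    return make_folded_sheet(human_profile(), resolution=0.25, seed=3)


@pytest.fixture(scope="session")
def human_parcellation(human_mesh):
    return make_parcellation(human_mesh, "human-default")


@pytest.fixture(scope="session")
def macaque_mesh():
    return make_folded_sheet(macaque_profile(), resolution=0.6, seed=3)


@pytest.fixture(scope="session")
def macaque_parcellation(macaque_mesh):
    return make_parcellation(macaque_mesh, "macaque-default")


@pytest.fixture()
def small_flat_mesh():
    return lattice_mesh(10, 10)


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale human config: small patch, coarse coil, short run."""
    return RunConfig(
        species="human",
        profile_overrides={"extent": (60.0, 60.0)},
        resolution=0.35,
        coil_segments_per_loop=16,
        n_timepoints=120,
        amplitudes={n: amplitude_for_correlation(0.8, 1.0) for n in range(1, 8)},
        seed=11,
    )
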