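"""Synthetic folded cortical patches, parcellations, and point-to-surface mapping.

The surfaces generated here are rectangular sheets ``z = f(x, y)`` triangulated
row-major, standing in for a cortical patch.  Coordinate convention (fixed,
used throughout the package): right-handed, units mm, the sheet lies near
``z = 0`` and the coil approaches from ``+z``; "medial" is the minimum-x edge
and "anterior" the maximum-y edge.

Two species profiles are bundled: a large multi-gyral "human-like" patch and a
smaller "macaque-like" patch with a single dominant gyrus flanked by two sulci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, ParameterError

__all__ = [
    "SurfaceMesh",
    "SpeciesProfile",
    "ParcellationMap",
    "BandLayout",
    "NETWORK_NAMES",
    "NETWORK_IDS",
    "make_folded_sheet",
    "make_parcellation",
    "map_points_to_surface",
]

#: Canonical 7-network labels; 0 is the unassigned / medial-wall label.
NETWORK_NAMES = {
    0: "Unassigned",
    1: "Visual",
    2: "SN",
    3: "DAN",
    4: "VAN",
    5: "Limbic",
    6: "FPN",
    7: "DN",
}
NETWORK_IDS = {name: nid for nid, name in NETWORK_NAMES.items()}

MULTI_GYRAL = "multi-gyral"
SINGLE_DOMINANT = "single-dominant-gyrus"


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated surface patch.

    Attributes
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex-index triples
    normals : (V, 3) float array of unit outward (+z-facing) vertex normals
    grid_shape : optional (n_rows, n_cols) lattice shape for sheets generated
        by :func:`make_folded_sheet` (rows run along y, columns along x).
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        n = np.asarray(self.normals, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 3:
            raise InputError("vertices must be a (V>=3, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 1:
            raise InputError("faces must be a (F>=1, 3) array")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise InputError("face indices out of vertex range")
        if n.shape != v.shape:
            raise InputError("normals must match vertices in shape")
        norms = np.linalg.norm(n, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise InputError("vertex normals must have unit length")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        object.__setattr__(self, "normals", n)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)


@dataclass(frozen=True)
class SpeciesProfile:
    """Geometry parameters for one species-flavoured synthetic patch.

    ``extent`` is the patch size in mm (x span, y span); ``spacing`` is the
    coil-grid step; ``standoff`` is the baseline coil-to-surface distance.
    """

    name: str
    extent: tuple[float, float]
    spacing: float
    fold_amplitude: float
    fold_wavelength: float
    fold_layout: str
    standoff: float

    def __post_init__(self) -> None:
        if self.spacing <= 0 or self.standoff <= 0 or self.fold_wavelength <= 0:
            raise ParameterError("spacing, standoff and wavelength must be > 0")
        if self.fold_amplitude < 0:
            raise ParameterError("fold amplitude must be >= 0")
        if any(e <= 0 for e in self.extent):
            raise ParameterError("extent must be positive in both directions")
        if self.fold_layout not in (MULTI_GYRAL, SINGLE_DOMINANT):
            raise ParameterError(f"unknown fold layout {self.fold_layout!r}")

    def with_overrides(self, **kwargs) -> "SpeciesProfile":
        return replace(self, **kwargs)


def human_profile(**overrides) -> SpeciesProfile:
    """Default human-like patch: large, multi-gyral, 10 mm coil grid."""
    p = SpeciesProfile(
        name="human-like",
        extent=(120.0, 120.0),
        spacing=10.0,
        fold_amplitude=8.0,
        fold_wavelength=30.0,
        fold_layout=MULTI_GYRAL,
        standoff=12.0,
    )
    return p.with_overrides(**overrides) if overrides else p


def macaque_profile(**overrides) -> SpeciesProfile:
    """Default macaque-like patch: small, one dominant gyrus, 5 mm coil grid."""
    p = SpeciesProfile(
        name="macaque-like",
        extent=(44.0, 44.0),
        spacing=5.0,
        fold_amplitude=8.0,
        fold_wavelength=22.0,
        fold_layout=SINGLE_DOMINANT,
        standoff=3.0,
    )
    return p.with_overrides(**overrides) if overrides else p


def _height_profile(x: np.ndarray, profile: SpeciesProfile) -> np.ndarray:
    """Cross-fold height f(x); folds run along y and vary along x."""
    amp, lam = profile.fold_amplitude, profile.fold_wavelength
    if profile.fold_layout == MULTI_GYRAL:
        return amp * np.cos(2.0 * np.pi * x / lam)
    # Single dominant gyrus: Ricker profile, one central crown flanked by two
    # sulci at x = +-sqrt(3)*s; monotone tails, so any centre transect has
    # exactly one interior local maximum.
    s = lam / (2.0 * np.sqrt(3.0))
    u = (x / s) ** 2
    return amp * (1.0 - u) * np.exp(-u / 2.0)


def make_folded_sheet(
    profile: SpeciesProfile, resolution: float = 0.5, seed: int = 0
) -> SurfaceMesh:
    """Generate a folded rectangular sheet for a species profile.

    Parameters
    ----------
    resolution : vertices per mm along each axis.
    seed : RNG seed for the small low-frequency surface undulation (pure
        function of ``(profile, resolution, seed)``).
    """
    if resolution <= 0:
        raise ParameterError("resolution must be > 0")
    ex, ey = profile.extent
    nx = int(round(ex * resolution)) + 1
    ny = int(round(ey * resolution)) + 1
    if nx < 20 or ny < 20:
        raise ParameterError(
            f"resolution {resolution} yields a {ny}x{nx} lattice; need >= 20x20"
        )
    x = np.linspace(-ex / 2.0, ex / 2.0, nx)
    y = np.linspace(-ey / 2.0, ey / 2.0, ny)
    xx, yy = np.meshgrid(x, y)  # row-major: row index varies along y

    zx = _height_profile(x, profile)
    # Seeded undulation varies along y only, so it cannot change the count of
    # local maxima along any cross-fold (x) transect; scaled by the fold
    # amplitude so a zero-amplitude profile stays exactly flat.
    rng = np.random.default_rng(seed)
    k = rng.integers(1, 4)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    zy = 0.02 * profile.fold_amplitude * np.sin(2.0 * np.pi * k * y / ey + phase)
    zz = zx[None, :] + zy[:, None]

    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    # Two CCW (+z seen from above) triangles per lattice quad.
    iy, ix = np.meshgrid(np.arange(ny - 1), np.arange(nx - 1), indexing="ij")
    v00 = (iy * nx + ix).ravel()
    v10 = v00 + 1
    v01 = v00 + nx
    v11 = v01 + 1
    faces = np.concatenate(
        [
            np.column_stack([v00, v10, v11]),
            np.column_stack([v00, v11, v01]),
        ]
    )

    normals = _vertex_normals(vertices, faces)
    return SurfaceMesh(vertices, faces, normals, grid_shape=(ny, nx))


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted average of incident face normals, unit length."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    fn = np.cross(b - a, c - a)  # length = 2 * area, oriented +z
    vn = np.zeros_like(vertices)
    for j in range(3):
        np.add.at(vn, faces[:, j], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise InputError("degenerate vertex normal (isolated or flat-zero vertex)")
    return vn / norms


@dataclass(frozen=True)
class ParcellationMap:
    """Per-vertex network label in {0..7}; 0 = unassigned / medial wall."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1:
            raise InputError("labels must be a 1-D array")
        if lab.min() < 0 or lab.max() > 7:
            raise InputError("labels must lie in {0..7}")
        object.__setattr__(self, "labels", lab)

    @property
    def n_vertices(self) -> int:
        return self.labels.shape[0]

    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=8)


@dataclass(frozen=True)
class BandLayout:
    """Contiguous label bands along one patch axis.

    ``bands`` is an ordered list of ``(label, fractional_width)`` pairs laid
    out from the minimum edge of ``axis``; widths must sum to <= 1, leftover
    vertices get label 0.
    """

    bands: tuple[tuple[int, float], ...]
    axis: str = "x"

    def __post_init__(self) -> None:
        bands = tuple((int(l), float(w)) for l, w in self.bands)
        if len(bands) < 1:
            raise ParameterError("layout needs at least one band")
        if any(w <= 0 for _, w in bands):
            raise ParameterError("band widths must be > 0")
        if any(l < 0 or l > 7 for l, _ in bands):
            raise ParameterError("band labels must lie in {0..7}")
        total = sum(w for _, w in bands)
        if total > 1.0 + 1e-12:
            raise ParameterError(f"band widths sum to {total} > 1")
        if self.axis not in ("x", "y"):
            raise ParameterError("axis must be 'x' or 'y'")
        object.__setattr__(self, "bands", bands)


#: Fractional y-depth of the posterior SN/DAN/VAN strip in the default
#: human-like layout.
_HUMAN_POSTERIOR_FRAC = 0.15


def _fractional_coords(mesh: SurfaceMesh) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = mesh.bounds()
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    xf = (mesh.vertices[:, 0] - lo[0]) / span[0]
    yf = (mesh.vertices[:, 1] - lo[1]) / span[1]
    return xf, yf


def _human_default_labels(mesh: SurfaceMesh) -> np.ndarray:
    """DN medial / FPN lateral with a thin posterior SN-DAN-VAN strip."""
    xf, yf = _fractional_coords(mesh)
    labels = np.where(xf < 0.5, NETWORK_IDS["DN"], NETWORK_IDS["FPN"])
    post = yf < _HUMAN_POSTERIOR_FRAC
    labels = np.where(post & (xf < 1 / 3), NETWORK_IDS["SN"], labels)
    labels = np.where(post & (xf >= 1 / 3) & (xf < 2 / 3), NETWORK_IDS["DAN"], labels)
    labels = np.where(post & (xf >= 2 / 3), NETWORK_IDS["VAN"], labels)
    return labels.astype(np.int64)


def _macaque_default_labels(mesh: SurfaceMesh) -> np.ndarray:
    """FPN on the dominant gyral crown, SN posterior, small DN/DAN/VAN patches."""
    xf, yf = _fractional_coords(mesh)
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    crown = np.abs(xf - 0.5) <= 0.2
    labels[crown] = NETWORK_IDS["FPN"]  # dominant gyral crown, full length
    labels[(yf < 0.25) & ~crown] = NETWORK_IDS["SN"]  # posterior flanks
    anterior = yf >= 0.7
    labels[anterior & (xf < 0.12) & ~crown] = NETWORK_IDS["DN"]
    labels[anterior & (xf > 0.88) & ~crown] = NETWORK_IDS["DAN"]
    labels[(~anterior) & (yf >= 0.25) & (xf > 0.88) & ~crown] = NETWORK_IDS["VAN"]
    return labels


def make_parcellation(
    mesh: SurfaceMesh,
    layout: BandLayout | str,
    seed: int = 0,
) -> ParcellationMap:
    """Assign per-vertex network labels according to a layout.

    ``layout`` is either a :class:`BandLayout` or one of the named defaults
    ``"human-default"`` / ``"macaque-default"``.  The assignment is
    deterministic; ``seed`` is accepted for interface uniformity with the
    other generators.
    """
    if isinstance(layout, str):
        if layout == "human-default":
            return ParcellationMap(_human_default_labels(mesh))
        if layout == "macaque-default":
            return ParcellationMap(_macaque_default_labels(mesh))
        raise ParameterError(f"unknown named layout {layout!r}")

    xf, yf = _fractional_coords(mesh)
    coord = xf if layout.axis == "x" else yf
    labels = np.zeros(mesh.n_vertices, dtype=np.int64)
    total = sum(w for _, w in layout.bands)
    lo = 0.0
    for i, (lab, width) in enumerate(layout.bands):
        hi = lo + width
        if i == len(layout.bands) - 1 and total >= 1.0 - 1e-12:
            mask = (coord >= lo) & (coord <= hi + 1e-12)
        else:
            mask = (coord >= lo) & (coord < hi)
        labels[mask] = lab
        lo = hi
    return ParcellationMap(labels)


def map_points_to_surface(
    points: Sequence[Sequence[float]] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    mesh: SurfaceMesh,
) -> np.ndarray:
    """Nearest-point value transfer onto mesh vertices.

    Every vertex receives the value of its Euclidean-nearest input point;
    exact distance ties are broken by the lowest point index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    vals = np.asarray(values, dtype=np.float64)
    if pts.size == 0:
        raise InputError("point set must be non-empty")
    if pts.shape[1] != 3:
        raise InputError("points must be 3-D coordinates")
    if vals.shape[0] != pts.shape[0]:
        raise InputError("values must match points in length")

    tree = cKDTree(pts)
    dist, idx = tree.query(mesh.vertices)
    # Enforce the lowest-index tie-break, which cKDTree does not guarantee.
    tol = 1e-12 + 1e-9 * np.maximum(dist, 1.0)
    candidates = tree.query_ball_point(mesh.vertices, r=dist + tol)
    for v, cand in enumerate(candidates):
        if len(cand) > 1:
            d = np.linalg.norm(pts[cand] - mesh.vertices[v], axis=1)
            best = d.min()
            idx[v] = min(c for c, dc in zip(cand, d) if dc <= best + 1e-12)
    return vals[idx]
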