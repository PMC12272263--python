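"""Stimulation-grid enumeration, figure-8 coil primary fields, and EFSI.

The field model is the free-space primary field only: each coil loop is
discretized into straight segments, the magnetic vector potential ``A`` is
summed over segments at every vertex, and ``|E| = |dA/dt|``.  This is a
deliberate, documented stand-in for a conductivity-aware FEM solve — it keeps
the proximity physics (gyral crowns closer to the coil receive stronger
fields) without tissue modeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, GeometryError, InputError, ParameterError
from .surface import SpeciesProfile, SurfaceMesh

__all__ = [
    "CoilModel",
    "CoilPlacement",
    "EFieldMap",
    "EfsiMap",
    "ORIENTATIONS_DEG",
    "GRID_ROWS",
    "GRID_COLS",
    "build_grid",
    "loop_vector_potential",
    "primary_efield",
    "planted_field",
    "efsi",
    "per_map_suprathreshold_fraction",
]

MU0_OVER_4PI = 1e-7  # T*m/A

#: 12 coil orientations: 15-degree steps over a half circle, 0 = handle along
#: the midline (+y) reference.
ORIENTATIONS_DEG = tuple(range(0, 180, 15))
GRID_ROWS = 6
GRID_COLS = 6


@dataclass(frozen=True)
class CoilModel:
    """Planar figure-8 coil: two coplanar loops with opposite winding.

    ``radius_mm`` is the single-loop radius (default 35 mm, i.e. a 70 mm
    figure-8 coil); ``di_dt`` is the coil-current rate of change in A/s.
    """

    radius_mm: float = 35.0
    segments_per_loop: int = 64
    di_dt: float = 1.0e8

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError("coil radius must be > 0")
        if self.segments_per_loop < 8:
            raise ParameterError("need at least 8 segments per loop")
        if self.di_dt <= 0:
            raise ParameterError("dI/dt must be > 0")


@dataclass(frozen=True)
class CoilPlacement:
    """One grid location + orientation of the coil above the patch."""

    row: int
    col: int
    theta_deg: int
    center: np.ndarray  # (3,) mm
    handle: np.ndarray  # unit vector in the tangent plane
    normal: np.ndarray  # unit vector pointing toward the surface

    def __post_init__(self) -> None:
        if self.theta_deg not in ORIENTATIONS_DEG:
            raise ParameterError(f"theta {self.theta_deg} not in {ORIENTATIONS_DEG}")
        c = np.asarray(self.center, dtype=np.float64)
        h = np.asarray(self.handle, dtype=np.float64)
        n = np.asarray(self.normal, dtype=np.float64)
        for name, vec in (("handle", h), ("normal", n)):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-6:
                raise ParameterError(f"{name} must be a unit vector")
        if abs(float(h @ n)) > 1e-6:
            raise ParameterError("handle must be perpendicular to the coil normal")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "handle", h)
        object.__setattr__(self, "normal", n)

    @property
    def key(self) -> tuple[int, int, int]:
        return (self.row, self.col, self.theta_deg)


@dataclass(frozen=True)
class EFieldMap:
    """Per-vertex field magnitude |E| (V/m) for one placement."""

    values: np.ndarray
    placement: CoilPlacement | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise InputError("field values must be 1-D")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise InputError("field magnitudes must be finite and >= 0")
        object.__setattr__(self, "values", v)

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EfsiMap:
    """Per-vertex stimulation percentage in [0, 100]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if np.any(v < 0) or np.any(v > 100):
            raise InputError("EFSI values must lie in [0, 100]")
        object.__setattr__(self, "values", v)


def build_grid(profile: SpeciesProfile, mesh: SurfaceMesh) -> list[CoilPlacement]:
    """Enumerate the 6x6 location grid x 12 orientations (432 placements).

    Locations form a planar lattice at the profile's spacing, centred over the
    patch, at ``max(z) + standoff`` above the folds.  Orientation theta rotates
    the handle from the +y (midline) reference within the tangent plane.
    """
    lo, hi = mesh.bounds()
    span = (GRID_COLS - 1) * profile.spacing
    if span > (hi[0] - lo[0]) + 1e-9 or span > (hi[1] - lo[1]) + 1e-9:
        raise GeometryError(
            f"grid footprint {span} mm exceeds patch extent "
            f"({hi[0] - lo[0]:.1f} x {hi[1] - lo[1]:.1f} mm)"
        )
    cx = 0.5 * (lo[0] + hi[0])
    cy = 0.5 * (lo[1] + hi[1])
    z0 = hi[2] + profile.standoff
    normal = np.array([0.0, 0.0, -1.0])

    placements = []
    for row in range(GRID_ROWS):
        # Row 0 is the anterior (max-y) edge; rows advance posteriorly.
        y = cy + ((GRID_ROWS - 1) / 2.0 - row) * profile.spacing
        for col in range(GRID_COLS):
            # Col 0 is the medial (min-x) edge; columns advance laterally.
            x = cx + (col - (GRID_COLS - 1) / 2.0) * profile.spacing
            for theta in ORIENTATIONS_DEG:
                t = np.deg2rad(theta)
                handle = np.array([-np.sin(t), np.cos(t), 0.0])
                placements.append(
                    CoilPlacement(
                        row=row,
                        col=col,
                        theta_deg=theta,
                        center=np.array([x, y, z0]),
                        handle=handle,
                        normal=normal,
                    )
                )
    return placements


def _loop_segments(
    center: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    radius_mm: float,
    n_segments: int,
    winding: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Midpoints (mm) and directed segment vectors (mm) of a discretized loop
    in the plane spanned by unit vectors (u, v)."""
    ang = 2.0 * np.pi * np.arange(n_segments + 1) / n_segments
    if winding < 0:
        ang = ang[::-1]
    pts = center[None, :] + radius_mm * (
        np.cos(ang)[:, None] * u[None, :] + np.sin(ang)[:, None] * v[None, :]
    )
    mid = 0.5 * (pts[:-1] + pts[1:])
    dl = pts[1:] - pts[:-1]
    return mid, dl


def loop_vector_potential(
    points_mm: np.ndarray,
    center_mm: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    radius_mm: float,
    n_segments: int,
    winding: int = 1,
) -> np.ndarray:
    """Vector potential A (T*m per ampere) of one discretized circular loop.

    Straight-segment Biot-Savart quadrature: ``A = mu0/(4 pi) * sum dl / r``
    evaluated at segment midpoints, with all lengths converted to metres.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    mid, dl = _loop_segments(
        np.asarray(center_mm, float), np.asarray(u, float), np.asarray(v, float),
        radius_mm, n_segments, winding,
    )
    diff = pts[:, None, :] - mid[None, :, :]  # (P, M, 3) mm
    dist = np.linalg.norm(diff, axis=2)  # mm
    if np.any(dist < 1e-9):
        raise GeometryError("evaluation point coincides with a coil segment")
    # dl/r is dimensionless, so evaluating the ratio in mm equals metres.
    return MU0_OVER_4PI * (dl[None, :, :] / dist[:, :, None]).sum(axis=1)


def primary_efield(
    coil: CoilModel, placement: CoilPlacement, mesh: SurfaceMesh
) -> EFieldMap:
    """Free-space primary field |E| = |dA/dt| of the figure-8 coil at every
    vertex.  The two loops sit side by side across the handle axis and carry
    opposite winding, so their contributions add beneath the intersection."""
    side = np.cross(placement.handle, placement.normal)
    side /= np.linalg.norm(side)
    u, v = placement.handle, side
    a_total = np.zeros((mesh.n_vertices, 3))
    for sign in (+1, -1):
        loop_center = placement.center + sign * coil.radius_mm * side
        a_total += loop_vector_potential(
            mesh.vertices, loop_center, u, v, coil.radius_mm,
            coil.segments_per_loop, winding=sign,
        )
    e_mag = coil.di_dt * np.linalg.norm(a_total, axis=1)
    return EFieldMap(e_mag, placement)


def planted_field(mesh: SurfaceMesh, center_vertex: int, spread_mm: float) -> EFieldMap:
    """Gaussian fall-off test field: ``exp(-d^2 / (2 spread^2))`` with
    Euclidean distance d from the centre vertex (value exactly 1 there)."""
    if not 0 <= center_vertex < mesh.n_vertices:
        raise InputError(f"vertex index {center_vertex} out of range")
    if spread_mm <= 0:
        raise ParameterError("spread must be > 0")
    d2 = np.sum((mesh.vertices - mesh.vertices[center_vertex]) ** 2, axis=1)
    return EFieldMap(np.exp(-d2 / (2.0 * spread_mm**2)))


def _check_field_stack(fields: Sequence[EFieldMap]) -> np.ndarray:
    if len(fields) == 0:
        raise InputError("need at least one field map")
    n = fields[0].n_vertices
    if any(f.n_vertices != n for f in fields):
        raise InputError("all field maps must share one mesh")
    stack = np.stack([f.values for f in fields])
    if np.any(stack.max(axis=1) <= 0):
        raise DegenerateInputError("all-zero field map in EFSI input")
    return stack


def efsi(fields: Sequence[EFieldMap], threshold_fraction: float = 0.5) -> EfsiMap:
    """Electric field stimulation index.

    Per vertex: the percentage of maps in which the vertex's field strictly
    exceeds ``threshold_fraction`` x that map's maximum.  (The per-map
    complementary summary is :func:`per_map_suprathreshold_fraction`.)
    """
    if not 0 < threshold_fraction < 1:
        raise ParameterError("threshold fraction must lie in (0, 1)")
    stack = _check_field_stack(fields)
    above = stack > threshold_fraction * stack.max(axis=1, keepdims=True)
    return EfsiMap(100.0 * above.mean(axis=0))


def per_map_suprathreshold_fraction(
    fields: Sequence[EFieldMap], threshold_fraction: float = 0.5
) -> np.ndarray:
    """Per map: percentage of vertices strictly above ``fraction x max``."""
    if not 0 < threshold_fraction < 1:
        raise ParameterError("threshold fraction must lie in (0, 1)")
    stack = _check_field_stack(fields)
    above = stack > threshold_fraction * stack.max(axis=1, keepdims=True)
    return 100.0 * above.mean(axis=1)
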