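"""Low-level 3D primitives for femoral axis measurement.

The measurement procedure reduces to a handful of geometric operations:
least-squares circle fits on cross-section point clouds (medullary canal,
intercondylar-notch apex), construction of the anatomical and mechanical
axes, the transverse plane perpendicular to the mechanical axis, projection
of reference axes into that plane, and signed in-plane angles between
(undirected) alignment lines.

Conventions
-----------
* All lengths in millimetres, all angles in degrees unless noted.
* Plane normals are oriented distal-to-proximal along the mechanical axis.
* Anatomical alignment lines are undirected: in-plane angles are normalized
  to ``(-90, 90]`` by flipping the sign of one direction where needed.
* The *external-rotation-positive* sign is realized as the right-handed
  (counterclockwise about the plane normal) sense for a right femur and the
  mirrored sense for a left femur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import (
    DegenerateAxisError,
    DegenerateFitError,
    DegenerateProjectionError,
)

Side = Literal["left", "right"]

#: Tolerance for exact geometric identities (unit norms, coplanarity checks).
EXACT_TOL = 1e-9
#: Tolerance (degrees) for noise-free pipeline round trips.
ROUNDTRIP_TOL_DEG = 1e-6
#: Maximum out-of-plane distance (mm) tolerated for cross-section points.
SECTION_COPLANARITY_TOL = 0.1


def _unit(v: np.ndarray, *, err: type[Exception] = ValueError, what: str = "vector") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < EXACT_TOL:
        raise err(f"zero-norm {what}")
    return v / n


def side_sign(side: Side) -> float:
    """Chirality factor: +1 for a right femur, -1 for a left femur."""
    if side == "right":
        return 1.0
    if side == "left":
        return -1.0
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass(frozen=True)
class Line3:
    """A 3D line through ``point`` with unit ``direction``."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", _unit(self.direction, what="line direction"))

    def canonical_direction(self) -> np.ndarray:
        """Direction with a sign fixed by lexicographic convention (for undirected comparison)."""
        d = self.direction
        for c in d:
            if abs(c) > EXACT_TOL:
                return d if c > 0 else -d
        return d


@dataclass(frozen=True)
class Plane3:
    """A plane through ``point`` with unit ``normal`` (distal-to-proximal)."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal, what="plane normal"))

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, dtype=float) - self.point, self.normal))


@dataclass(frozen=True)
class CrossSection:
    """A coplanar point cloud with its supporting plane."""

    points: np.ndarray  # (n, 3)
    section_plane: Plane3

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 3 or pts.shape[1] != 3:
            raise DegenerateFitError("a cross-section needs at least 3 points in 3D")
        object.__setattr__(self, "points", pts)
        d = pts - self.section_plane.point
        off = np.abs(d @ self.section_plane.normal)
        if np.max(off) > SECTION_COPLANARITY_TOL:
            raise DegenerateFitError(
                f"cross-section points up to {np.max(off):.3g} mm out of plane "
                f"(tolerance {SECTION_COPLANARITY_TOL} mm)"
            )

    @classmethod
    def from_points(cls, points: np.ndarray) -> "CrossSection":
        """Build a section from points alone, fitting the plane by SVD.

        The normal sign is arbitrary; circle fitting does not depend on it.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[0] < 3:
            raise DegenerateFitError("need at least 3 points to define a section plane")
        centroid = pts.mean(axis=0)
        _, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
        if s[1] < EXACT_TOL:
            raise DegenerateFitError("section points are collinear")
        return cls(points=pts, section_plane=Plane3(point=centroid, normal=vt[2]))


def _plane_basis(plane: Plane3) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane vectors."""
    n = plane.normal
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(seed - np.dot(seed, n) * n)
    e2 = np.cross(n, e1)
    return e1, e2


def fit_circle(section: CrossSection) -> tuple[np.ndarray, float]:
    """Algebraic (Kåsa) least-squares circle fit in the section plane.

    Solves the linear system for center ``(a, b)`` and radius that minimizes
    the algebraic residual ``x^2 + y^2 - 2ax - 2by - c``. Exact for points
    lying exactly on a circle. The center is returned in 3D coordinates.

    Raises
    ------
    DegenerateFitError
        If the in-plane points are collinear.
    """
    e1, e2 = _plane_basis(section.section_plane)
    rel = section.points - section.section_plane.point
    x = rel @ e1
    y = rel @ e2
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    # Collinear points make the normal equations singular.
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max())) < 3:
        raise DegenerateFitError("circle fit on collinear points")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a, c, d = sol
    r2 = d + a**2 + c**2
    if r2 <= 0:
        raise DegenerateFitError("circle fit produced non-positive radius")
    center3 = section.section_plane.point + a * e1 + c * e2
    return center3, float(math.sqrt(r2))


def anatomical_axis(canal_center: np.ndarray, notch_apex_center: np.ndarray) -> Line3:
    """Line through the shaft-canal and notch-apex circle centers.

    Oriented distal-to-proximal: from the notch apex (distal) toward the
    medullary-canal center (proximal).
    """
    canal = np.asarray(canal_center, dtype=float)
    notch = np.asarray(notch_apex_center, dtype=float)
    d = canal - notch
    if np.linalg.norm(d) < EXACT_TOL:
        raise DegenerateAxisError("canal and notch-apex centers coincide")
    return Line3(point=notch, direction=d)


def mechanical_axis(
    anat: Line3, alpha_deg: float, side: Side, anterior: np.ndarray
) -> Line3:
    """Mechanical axis obtained by a varus rotation of the anatomical axis.

    The anatomical axis is rotated by the valgus angle ``alpha_deg`` within
    the coronal plane, i.e. about the anterior-posterior direction
    (orthogonalized against the axis so the rotation angle is exact), in the
    varus sense appropriate to ``side``. The returned line passes through
    ``anat.point`` (the knee center) and makes exactly ``alpha_deg`` with the
    anatomical axis.
    """
    if not 0 <= alpha_deg < 45:
        raise ValueError(f"valgus angle must be in [0, 45), got {alpha_deg}")
    u = anat.direction
    ant = np.asarray(anterior, dtype=float)
    ax = ant - np.dot(ant, u) * u
    if np.linalg.norm(ax) < EXACT_TOL:
        raise DegenerateAxisError("anterior direction parallel to the anatomical axis")
    ax = ax / np.linalg.norm(ax)
    phi = -side_sign(side) * math.radians(alpha_deg)
    # Rodrigues rotation; the n (n·u) term vanishes since ax ⟂ u.
    rotated = u * math.cos(phi) + np.cross(ax, u) * math.sin(phi)
    return Line3(point=anat.point, direction=rotated)


def transverse_plane(mech: Line3, through: np.ndarray) -> Plane3:
    """Plane perpendicular to the mechanical axis, containing ``through``."""
    return Plane3(point=np.asarray(through, dtype=float), normal=mech.direction)


def project_direction(d: np.ndarray, plane: Plane3) -> np.ndarray:
    """Unit component of ``d`` orthogonal to the plane normal.

    Idempotent on in-plane directions. Raises DegenerateProjectionError when
    ``d`` is (numerically) parallel to the plane normal.
    """
    d = np.asarray(d, dtype=float)
    n = plane.normal
    in_plane = d - np.dot(d, n) * n
    norm = np.linalg.norm(in_plane)
    if norm < EXACT_TOL:
        raise DegenerateProjectionError("direction is parallel to the plane normal")
    return in_plane / norm


def _wrap_line_angle(theta_deg: float) -> float:
    """Normalize an undirected-line angle to (-90, 90]."""
    t = math.fmod(theta_deg, 180.0)
    if t > 90.0:
        t -= 180.0
    elif t <= -90.0:
        t += 180.0
    return t


def signed_angle(d_ref: np.ndarray, d_meas: np.ndarray, plane: Plane3, side: Side) -> float:
    """Signed in-plane angle (degrees) from ``d_ref`` to ``d_meas``.

    Positive means ``d_meas`` is externally rotated relative to ``d_ref``;
    for a right femur with a distal-to-proximal normal this is the
    counterclockwise sense about the normal, mirrored for a left femur.
    Both inputs are treated as undirected lines, so the result is normalized
    to ``(-90, 90]``.
    """
    a = _unit(np.asarray(d_ref, dtype=float), what="reference direction")
    b = _unit(np.asarray(d_meas, dtype=float), what="measured direction")
    n = plane.normal
    raw = math.degrees(math.atan2(float(np.dot(n, np.cross(a, b))), float(np.dot(a, b))))
    return _wrap_line_angle(side_sign(side) * raw)


def rotate_in_plane(
    d: np.ndarray,
    degrees: float,
    plane: Plane3,
    sense: Literal["external", "internal"],
    side: Side,
) -> np.ndarray:
    """Rotate an in-plane direction by ``degrees`` in the given anatomical sense.

    ``signed_angle(d, rotate_in_plane(d, t, 'external'), plane, side) == +t``
    for ``t`` in (0, 90].
    """
    if sense not in ("external", "internal"):
        raise ValueError(f"sense must be 'external' or 'internal', got {sense!r}")
    d = _unit(np.asarray(d, dtype=float), what="direction")
    sgn = side_sign(side) * (1.0 if sense == "external" else -1.0)
    phi = sgn * math.radians(degrees)
    n = plane.normal
    return d * math.cos(phi) + np.cross(n, d) * math.sin(phi) + n * np.dot(n, d) * (1 - math.cos(phi))


def angle_between_lines(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned acute angle (degrees) between two undirected directions, in [0, 90]."""
    a = _unit(np.asarray(u, dtype=float), what="direction")
    b = _unit(np.asarray(v, dtype=float), what="direction")
    c = min(1.0, abs(float(np.dot(a, b))))
    return math.degrees(math.acos(c))
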