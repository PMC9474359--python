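"""Exact 3D primitives for landmark morphometry.

All coordinates are world millimetres in the LPS frame (+x toward the
patient's left, +y posterior, +z superior — the DICOM patient frame).
Planes are stored in Hessian normal form (unit normal ``n``, scalar offset
``d``; the plane is the locus of points ``p`` with ``n·p = d``), and the
line–plane angle is the complement of the angle between the segment and the
plane normal: ``arcsin(|n·d̂|)``, always in [0°, 90°].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "Point3",
    "ReferencePlane",
    "RigidTransform",
    "plane_from_points",
    "line_plane_angle_deg",
    "distance_mm",
    "apply_rigid",
]

#: triangle-area floor (mm^2) below which three points are treated as collinear
COLLINEARITY_AREA_TOL = 1e-9


@dataclass(frozen=True)
class Point3:
    """A 3D world coordinate in millimetres (LPS frame)."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"Point3.{name} must be finite, got {v!r}")
            object.__setattr__(self, name, float(v))

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a) -> "Point3":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise ValidationError(f"expected a 3-vector, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]))


def _as_vec(p) -> np.ndarray:
    if isinstance(p, Point3):
        return p.to_array()
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValidationError(f"expected a Point3 or 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValidationError("coordinates must be finite")
    return a


@dataclass(frozen=True)
class ReferencePlane:
    """A plane ``{p : normal·p = offset}`` with |normal| = 1.

    ``defining_points`` records the three (label, Point3) pairs the plane was
    built from, in construction order; purely informational.
    """

    normal: np.ndarray
    offset: float
    defining_points: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if n.shape != (3,):
            raise ValidationError("plane normal must be a 3-vector")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValidationError("plane normal must be unit length")
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    def signed_distance(self, p) -> float:
        """Signed distance (mm) from ``p`` to the plane, positive on the
        normal side."""
        return float(self.normal @ _as_vec(p) - self.offset)

    def project(self, p) -> np.ndarray:
        """Orthogonal projection of ``p`` onto the plane (as an ndarray)."""
        v = _as_vec(p)
        return v - self.signed_distance(v) * self.normal


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p ↦ R p + t`` (rotation + translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-9):
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValidationError("rotation matrix has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first,
        then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _fix_normal_sign(n: np.ndarray) -> np.ndarray:
    # superior (z >= 0) convention; ties broken by first nonzero component > 0
    if n[2] != 0.0:
        return n if n[2] > 0 else -n
    for c in n:
        if c != 0.0:
            return n if c > 0 else -n
    return n


def plane_from_points(p1, p2, p3, labels: tuple[str, str, str] | None = None) -> ReferencePlane:
    """Build the plane through three non-collinear points.

    The normal is the normalised cross product of (p2−p1) and (p3−p1), with
    its sign fixed so the z-component is non-negative (so "superior" is
    well-defined); angle computations use the absolute dot product and are
    unaffected by the convention.

    Parameters
    ----------
    p1, p2, p3 : Point3 or array-like
        Pairwise-distinct, non-collinear points (triangle area > 1e-9 mm²).
    labels : optional triple of landmark identifiers, used in error messages
        and recorded on the returned plane.

    Raises
    ------
    GeometryError
        If the points are coincident or collinear.
    """
    a, b, c = _as_vec(p1), _as_vec(p2), _as_vec(p3)
    lab = labels if labels is not None else ("p1", "p2", "p3")
    cross = np.cross(b - a, c - a)
    area2 = np.linalg.norm(cross)  # twice the triangle area
    if area2 / 2.0 <= COLLINEARITY_AREA_TOL:
        raise GeometryError(
            "cannot build a plane from degenerate (collinear or coincident) "
            f"points {lab[0]}={tuple(a)}, {lab[1]}={tuple(b)}, {lab[2]}={tuple(c)}"
        )
    n = _fix_normal_sign(cross / area2)
    # mean of the three dots: symmetric in the points, residual < machine eps
    offset = float(np.mean([n @ a, n @ b, n @ c]))
    pts = tuple(
        (str(l), Point3.from_array(v)) for l, v in zip(lab, (a, b, c))
    )
    return ReferencePlane(n, offset, pts)


def distance_mm(a, b) -> float:
    """Euclidean distance between two points, in millimetres."""
    return float(np.linalg.norm(_as_vec(b) - _as_vec(a)))


def line_plane_angle_deg(a, b, plane: ReferencePlane) -> float:
    """Angle between segment ``ab`` and a plane, in degrees in [0, 90].

    Computed as ``arcsin(|normal·d̂|)`` with ``d̂`` the unit direction of the
    segment; direction-agnostic (swapping a and b changes nothing).

    Raises
    ------
    GeometryError
        If ``a`` and ``b`` coincide (zero-length segment).
    """
    va, vb = _as_vec(a), _as_vec(b)
    d = vb - va
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise GeometryError(f"zero-length segment: both endpoints at {tuple(va)}")
    s = abs(float(plane.normal @ (d / norm)))
    s = min(s, 1.0)  # guard rounding just above 1
    return math.degrees(math.asin(s))


def apply_rigid(t: RigidTransform, p):
    """Apply a rigid transform to a point; returns the same flavour
    (Point3 in → Point3 out, array in → array out)."""
    v = t.rotation @ _as_vec(p) + t.translation
    if isinstance(p, Point3):
        return Point3.from_array(v)
    return v


def apply_rigid_to_plane(t: RigidTransform, plane: ReferencePlane) -> ReferencePlane:
    """Transform a plane by a rigid motion (normal rotates, offset shifts)."""
    n = _fix_normal_sign(t.rotation @ plane.normal)
    # pick a point on the old plane, move it, recompute the offset
    p0 = t.rotation @ (plane.offset * plane.normal) + t.translation
    pts = tuple((l, apply_rigid(t, p)) for l, p in plane.defining_points)
    return ReferencePlane(n, float(n @ p0), pts)
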