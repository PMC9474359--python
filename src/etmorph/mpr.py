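"""Minimal multiplanar-reconstruction (MPR) engine.

Resamples an oblique slice through any reference plane of a voxel volume by
trilinear interpolation, and recovers labelled marker positions from phantom
volumes. Voxel convention: world = origin + index·spacing with 0-based
indices addressing voxel *centers*; only identity-direction volumes are
supported (axis k of the grid runs along world axis k), which keeps the
engine unambiguous. Coordinates are interpreted in the LPS millimetre frame
used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .geometry import Point3, ReferencePlane

__all__ = ["VoxelVolume", "ObliqueSlice", "reformat_plane", "detect_marker_centroids"]


@dataclass(frozen=True)
class VoxelVolume:
    """A scalar voxel grid with per-axis spacing (mm) and world origin
    (the center of voxel (0, 0, 0))."""

    data: np.ndarray
    spacing: np.ndarray
    origin: Point3

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        sp = np.asarray(self.spacing, dtype=float)
        if data.ndim != 3 or data.size == 0:
            raise ValidationError("volume data must be a non-empty 3D array")
        if sp.shape != (3,) or not np.all(sp > 0):
            raise ValidationError("spacing must be three positive values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin.to_array() + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, world) -> np.ndarray:
        """Continuous (fractional) voxel index of a world point."""
        return (np.asarray(world, dtype=float) - self.origin.to_array()) / self.spacing

    def center_world(self) -> np.ndarray:
        return self.index_to_world((np.array(self.shape) - 1) / 2.0)

    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin.to_array()
        return a

    def save(self, path) -> None:
        """Write as NIfTI; the affine encodes spacing and origin (identity
        direction)."""
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "VoxelVolume":
        """Read a NIfTI volume; the affine is authoritative and must be
        identity-direction (diagonal, positive scales)."""
        img = nib.load(str(path))
        aff = np.asarray(img.affine, dtype=float)
        rot = aff[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValidationError(
                "only identity-direction volumes are supported (affine has "
                "off-diagonal rotation/shear terms)"
            )
        scales = np.diag(rot)
        if not np.all(scales > 0):
            raise ValidationError("affine scales must be positive (no axis flips)")
        data = np.asarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        return cls(data, scales, Point3.from_array(aff[:3, 3]))


@dataclass(frozen=True)
class ObliqueSlice:
    """A 2D reformat: values sampled on a plane, with the in-plane frame
    (orthonormal u, v both orthogonal to the plane normal), the world
    position of pixel (0, 0), and the isotropic in-plane spacing (mm)."""

    data: np.ndarray
    u: np.ndarray
    v: np.ndarray
    origin: Point3
    spacing: float

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        for name, w in (("u", u), ("v", v)):
            if abs(np.linalg.norm(w) - 1.0) > 1e-9:
                raise ValidationError(f"in-plane basis vector {name} must be unit")
        if abs(u @ v) > 1e-9:
            raise ValidationError("in-plane basis vectors must be orthogonal")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "data", np.asarray(self.data, dtype=float))

    def pixel_to_world(self, i, j) -> np.ndarray:
        return (self.origin.to_array()
                + np.multiply.outer(np.asarray(i, float) * self.spacing, self.u)
                + np.multiply.outer(np.asarray(j, float) * self.spacing, self.v))

    def world_to_pixel(self, world) -> np.ndarray:
        rel = np.asarray(world, dtype=float) - self.origin.to_array()
        return np.array([rel @ self.u, rel @ self.v]) / self.spacing

    def save(self, path) -> None:
        """Write as a 1-voxel-thick NIfTI volume carrying the true oblique
        affine (columns u·spacing, v·spacing, plane normal)."""
        n = np.cross(self.u, self.v)
        aff = np.eye(4)
        aff[:3, 0] = self.u * self.spacing
        aff[:3, 1] = self.v * self.spacing
        aff[:3, 2] = n
        aff[:3, 3] = self.origin.to_array()
        img = nib.Nifti1Image(self.data[:, :, None].astype(np.float32), aff)
        nib.save(img, str(path))


def reformat_plane(vol: VoxelVolume, plane: ReferencePlane, spacing: float,
                   extent: float, fill: float = 0.0) -> ObliqueSlice:
    """Extract an oblique slice of ``extent`` × ``extent`` mm through
    ``plane``, sampled at ``spacing`` mm by trilinear interpolation.

    The sample grid is centered at the projection of the volume center onto
    the plane. The in-plane axis u is the normalised projection of world +x
    onto the plane (falling back to +y when +x is within 1e-6 of the
    normal), and v = normal × u. Samples outside the volume take ``fill``.
    """
    if spacing <= 0:
        raise ValidationError("slice spacing must be positive")
    npix = int(round(extent / spacing))
    if npix < 1:
        raise ValidationError("extent must cover at least one sample at this spacing")
    n = plane.normal
    u = np.array([1.0, 0.0, 0.0])
    u = u - (u @ n) * n
    if np.linalg.norm(u) < 1e-6:
        u = np.array([0.0, 1.0, 0.0])
        u = u - (u @ n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    center = plane.project(vol.center_world())
    offs = (np.arange(npix) - (npix - 1) / 2.0) * spacing
    pts = (center[None, None, :]
           + offs[:, None, None] * u[None, None, :]
           + offs[None, :, None] * v[None, None, :])
    idx = (pts - vol.origin.to_array()) / vol.spacing
    values = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float),
        [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
        order=1, mode="constant", cval=float(fill),
    ).reshape(npix, npix)
    origin = Point3.from_array(center + offs[0] * u + offs[0] * v)
    return ObliqueSlice(values, u, v, origin, float(spacing))


def trilinear_sample(vol: VoxelVolume, world_points) -> np.ndarray:
    """Trilinear interpolation of the volume at world points (n×3)."""
    pts = np.atleast_2d(np.asarray(world_points, dtype=float))
    idx = (pts - vol.origin.to_array()) / vol.spacing
    return ndimage.map_coordinates(np.asarray(vol.data, dtype=float), idx.T,
                                   order=1, mode="constant", cval=0.0)


def detect_marker_centroids(vol: VoxelVolume) -> dict[int, Point3]:
    """Locate labelled markers: for each positive integer label, the
    intensity-weighted centroid of its voxels in world millimetres.

    Disconnected voxels carrying the same label (6-connectivity) are merged
    into one marker, as the label identifies the marker.
    """
    data = np.asarray(vol.data)
    labels = np.unique(data[data > 0])
    if labels.size == 0:
        raise ValidationError("volume contains no positive-labelled voxels")
    out: dict[int, Point3] = {}
    for lab in labels:
        idx = np.argwhere(data == lab).astype(float)
        w = data[data == lab].astype(float)
        centroid_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
        out[int(lab)] = Point3.from_array(vol.index_to_world(centroid_idx))
    return out
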