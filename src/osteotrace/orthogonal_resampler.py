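"""Locally-orthogonal slice resampling along a bone centerline.

The scanner acquires slices perpendicular to its own z axis, so an
obliquely placed bone shows elliptical, orientation-dependent
cross-sections.  To measure cortical geometry independently of how the
animal lay in the scanner, a local orthonormal frame (e_x', e_y', e_z')
is erected at every centerline position: e_z' is the local centerline
tangent, e_y' the (normalized) rotation axis between the scanner z axis
and e_z', and e_x' = e_y' x e_z' closes a right-handed basis.  Slices are
then resampled on a square grid in the (x', y') plane through trilinear
interpolation, at the stack's native voxel spacing.

The only assumption is that the bone is approximately straight locally:
the tangent comes from symmetric finite differences on a moving-average
smoothed centerline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .bone_tracker import Centerline

__all__ = [
    "LocalFrame",
    "OrthogonalSlice",
    "smooth_centerline",
    "local_tangent",
    "build_frame",
    "resample_orthogonal",
    "orthogonal_stack",
    "arc_length_positions",
]

_EZ = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal bone-centered frame at one centerline position.

    ``forward`` maps scanner-space offsets to bone coordinates (rows are
    the basis vectors); ``inverse`` maps back.  For an orthonormal basis
    the inverse is the transpose.
    """

    origin: np.ndarray  # (x, y, z) voxel coordinates
    e_x: np.ndarray
    e_y: np.ndarray
    e_z: np.ndarray

    @property
    def forward(self) -> np.ndarray:
        return np.vstack([self.e_x, self.e_y, self.e_z])

    @property
    def inverse(self) -> np.ndarray:
        return self.forward.T

    def to_bone(self, points: np.ndarray) -> np.ndarray:
        """Scanner coordinates -> bone coordinates (relative to origin)."""
        return (np.asarray(points) - self.origin) @ self.forward.T

    def to_scanner(self, points: np.ndarray) -> np.ndarray:
        """Bone coordinates -> scanner coordinates."""
        return np.asarray(points) @ self.forward + self.origin


@dataclass
class OrthogonalSlice:
    """A resampled cross-section orthogonal to the local bone axis."""

    pixels: np.ndarray  # (side, side), sampled in the (x', y') plane
    xi_mm: float  # arc-length distance above the joint
    frame: LocalFrame


def smooth_centerline(points: np.ndarray, window: int = 5) -> np.ndarray:
    """Moving-average smoothing of the in-plane centerline coordinates.

    The slice coordinate is left untouched; edges use nearest-value
    padding so endpoints stay anchored.
    """
    points = np.asarray(points, dtype=float)
    if window <= 1 or len(points) < 3:
        return points.copy()
    out = points.copy()
    out[:, 0] = uniform_filter1d(points[:, 0], size=window, mode="nearest")
    out[:, 1] = uniform_filter1d(points[:, 1], size=window, mode="nearest")
    return out


def local_tangent(points: np.ndarray, i: int, window: int = 5) -> np.ndarray:
    """Unit tangent of the centerline at row ``i`` by symmetric differences.

    The difference spans ``i - window .. i + window``, clamped one-sided
    at the ends, on the (already smoothed) centerline:
    e_z' ∝ (x_{i+w} − x_{i−w}, y_{i+w} − y_{i−w}, 2w).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 2:
        raise ValueError("centerline must contain at least 2 points")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    lo = max(i - window, 0)
    hi = min(i + window, n - 1)
    delta = points[hi] - points[lo]
    norm = np.linalg.norm(delta)
    if norm == 0:
        raise ValueError(f"degenerate tangent at index {i}")
    return delta / norm


def build_frame(e_z_prime: np.ndarray, origin: np.ndarray | None = None) -> LocalFrame:
    """Construct the local orthonormal frame from the tangent direction.

    e_y' is the normalized rotation axis e_z x e_z'; e_x' = e_y' x e_z'.
    If the tangent is (numerically) parallel to the scanner axis the
    rotation axis is undefined and the canonical identity frame is
    returned.
    """
    e_z_prime = np.asarray(e_z_prime, dtype=float)
    e_z_prime = e_z_prime / np.linalg.norm(e_z_prime)
    if origin is None:
        origin = np.zeros(3)
    axis = np.cross(_EZ, e_z_prime)
    axis_norm = np.linalg.norm(axis)
    if axis_norm < 1e-8:
        return LocalFrame(
            origin=np.asarray(origin, dtype=float),
            e_x=np.array([1.0, 0.0, 0.0]),
            e_y=np.array([0.0, 1.0, 0.0]),
            e_z=np.array([0.0, 0.0, 1.0]),
        )
    e_y = axis / axis_norm
    e_x = np.cross(e_y, e_z_prime)
    e_x = e_x / np.linalg.norm(e_x)
    return LocalFrame(
        origin=np.asarray(origin, dtype=float), e_x=e_x, e_y=e_y, e_z=e_z_prime
    )


def resample_orthogonal(
    volume: np.ndarray,
    frame: LocalFrame,
    half_extent: float,
    spacing: float = 1.0,
    binary: bool = False,
) -> np.ndarray:
    """Sample the plane through ``frame.origin`` spanned by e_x', e_y'.

    Each output pixel (u, v) samples the volume at
    ``origin + u*e_x' + v*e_y'`` by trilinear interpolation; samples
    outside the volume read as 0 (background).  Binary fields are
    interpolated as 0/1 floats and thresholded at 0.5, which avoids
    stair-step bias relative to nearest-neighbor lookup.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    ox, oy, oz = frame.origin
    nz, ny, nx = volume.shape
    if not (0 <= ox <= nx - 1 and 0 <= oy <= ny - 1 and 0 <= oz <= nz - 1):
        raise ValueError(f"frame origin {frame.origin} lies outside the volume")
    coords_1d = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    u, v = np.meshgrid(coords_1d, coords_1d, indexing="xy")
    pts = (
        frame.origin[None, :]
        + u.reshape(-1, 1) * frame.e_x[None, :]
        + v.reshape(-1, 1) * frame.e_y[None, :]
    )
    # map_coordinates indexes (z, y, x)
    sample_idx = pts[:, ::-1].T
    vals = map_coordinates(
        volume.astype(float), sample_idx, order=1, mode="constant", cval=0.0
    )
    plane = vals.reshape(u.shape)
    if binary:
        return plane >= 0.5
    return plane


def arc_length_positions(
    smoothed_points: np.ndarray, joint_z: int, voxel_size_um: float
) -> np.ndarray:
    """Arc-length coordinate xi (mm above the joint) per centerline row.

    xi accumulates the Euclidean step length between consecutive
    (smoothed) centerline points; the offset from the joint slice to the
    first tracked slice is extrapolated with the initial per-slice arc
    increment, so xi = 0 sits at the joint.
    """
    pts = np.asarray(smoothed_points, dtype=float)
    voxel_mm = voxel_size_um / 1000.0
    if len(pts) < 2:
        raise ValueError("need at least 2 centerline points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1) * voxel_mm
    xi0 = (pts[0, 2] - joint_z) / (pts[1, 2] - pts[0, 2]) * steps[0]
    return xi0 + np.concatenate([[0.0], np.cumsum(steps)])


def orthogonal_stack(
    volume: np.ndarray,
    centerline: Centerline,
    joint_z: int,
    half_extent: float,
    tangent_window: int = 5,
    smooth_window: int = 5,
    binary: bool = False,
) -> list[OrthogonalSlice]:
    """Resample one orthogonal cross-section per centerline slice.

    Returns the slices ordered along the bone with their arc-length
    positions xi (mm above the joint).
    """
    pts = smooth_centerline(centerline.points, window=smooth_window)
    xi = arc_length_positions(pts, joint_z, centerline.voxel_size_um)
    slices: list[OrthogonalSlice] = []
    for i in range(len(pts)):
        tangent = local_tangent(pts, i, window=tangent_window)
        frame = build_frame(tangent, origin=pts[i])
        pixels = resample_orthogonal(volume, frame, half_extent, binary=binary)
        slices.append(OrthogonalSlice(pixels=pixels, xi_mm=float(xi[i]), frame=frame))
    return slices
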