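"""Isolating one bone from a segmented stack by slice-to-slice tracking.

A bone is seeded manually: the user supplies one slice index, one point
inside the bone's cross-section on that slice, and the slice index of the
metatarsophalangeal joint.  Starting from the seeded connected region the
tracker walks slice by slice (in both directions) and, among the candidate
regions of the next slice whose footprint overlaps the previous region's
footprint (its "shadow"), picks the one with the smallest absolute area
difference.  Ties fall back to larger overlap, then smaller centroid
displacement — a continuity heuristic.

The per-slice centers of mass of the tracked region form the bone
centerline used downstream for orthogonal resampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .texture_segmentation import DEFAULT_VOXEL_SIZE_UM

__all__ = [
    "SeedAnnotation",
    "Centerline",
    "Region",
    "label_regions",
    "track_bone",
    "DEFAULT_RANGE_MM",
]

#: Longitudinal measurement window above the joint (mm): tracking starts
#: ~0.75 mm above the metatarsophalangeal joint (below that the spongy
#: bone has no marrow cavity) and extends to ~3.5 mm.
DEFAULT_RANGE_MM: tuple[float, float] = (0.75, 3.5)


@dataclass(frozen=True)
class SeedAnnotation:
    """Manual per-bone annotation: the only two user inputs of the pipeline.

    seed_slice/seed_point identify the bone; joint_z anchors the
    longitudinal coordinate xi = 0.
    """

    seed_slice: int
    seed_point: tuple[float, float]  # (x, y) within the bone on seed_slice
    joint_z: int

    def __post_init__(self) -> None:
        if self.seed_slice <= self.joint_z:
            raise ValueError(
                f"seed slice {self.seed_slice} must lie above the joint slice "
                f"{self.joint_z}"
            )


@dataclass
class Centerline:
    """Per-slice bone centers: rows of (x, y, z) with strictly increasing z."""

    points: np.ndarray  # (n, 3) float, columns x, y, z
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    areas_px: np.ndarray | None = None  # tracked region area per slice

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"centerline points must be (n, 3), got {self.points.shape}")
        z = self.points[:, 2]
        if len(z) > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("centerline slice indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def slices(self) -> np.ndarray:
        return self.points[:, 2].astype(int)


@dataclass(frozen=True)
class Region:
    """One connected foreground region of a slice."""

    label: int
    area: int
    centroid: tuple[float, float]  # (x, y)


def label_regions(mask_slice: np.ndarray) -> tuple[np.ndarray, list[Region]]:
    """8-connected components of one binary slice with areas and centroids."""
    mask_slice = np.asarray(mask_slice, dtype=bool)
    labeled = cc_label(mask_slice, connectivity=2)
    regions = [
        Region(label=p.label, area=int(p.area), centroid=(p.centroid[1], p.centroid[0]))
        for p in regionprops(labeled)
    ]
    return labeled, regions


def _select_successor(
    labeled: np.ndarray,
    regions: list[Region],
    prev_footprint: np.ndarray,
    prev_area: int,
    prev_centroid: tuple[float, float],
) -> Region | None:
    """Pick the region under the previous footprint with the closest area.

    Tie-breaks: larger overlap with the shadow, then smaller centroid
    displacement.
    """
    shadow_labels, shadow_counts = np.unique(labeled[prev_footprint], return_counts=True)
    overlap = dict(zip(shadow_labels.tolist(), shadow_counts.tolist()))
    overlap.pop(0, None)
    candidates = [r for r in regions if overlap.get(r.label, 0) > 0]
    if not candidates:
        return None

    def sort_key(r: Region):
        dx = r.centroid[0] - prev_centroid[0]
        dy = r.centroid[1] - prev_centroid[1]
        return (abs(r.area - prev_area), -overlap[r.label], np.hypot(dx, dy))

    return min(candidates, key=sort_key)


def track_bone(
    mask: np.ndarray,
    seed: SeedAnnotation,
    range_mm: tuple[float, float] = DEFAULT_RANGE_MM,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
) -> Centerline:
    """Track the seeded bone region through the measurement window.

    Parameters
    ----------
    mask : (n_slices, M, N) boolean bone mask.
    seed : the manual annotation; the connected region containing
        ``seed_point`` on ``seed_slice`` starts the track.
    range_mm : (near, far) distances above the joint (mm) delimiting the
        tracked slice interval.

    Tracking runs from the seed slice toward both interval ends.  If no
    candidate region overlaps the previous footprint the track is
    truncated there with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError(f"expected a 3D mask, got shape {mask.shape}")
    voxel_mm = voxel_size_um / 1000.0
    near, far = range_mm
    if not 0 <= near < far:
        raise ValueError(f"invalid measurement range {range_mm}")
    lo = seed.joint_z + int(np.ceil(near / voxel_mm))
    hi = seed.joint_z + int(np.floor(far / voxel_mm))
    lo = max(lo, 0)
    hi = min(hi, mask.shape[0] - 1)
    if lo > hi:
        raise ValueError(
            f"empty tracked range: slices [{lo}, {hi}] for joint_z={seed.joint_z} "
            f"and range {range_mm} mm at {voxel_size_um} μm voxels"
        )
    if not lo <= seed.seed_slice <= hi:
        raise ValueError(
            f"seed slice {seed.seed_slice} outside tracked slice range [{lo}, {hi}]"
        )

    labeled, regions = label_regions(mask[seed.seed_slice])
    sx, sy = seed.seed_point
    seed_label = int(labeled[int(round(sy)), int(round(sx))])
    if seed_label == 0:
        raise ValueError(
            f"seed point {seed.seed_point} is not on a foreground region of "
            f"slice {seed.seed_slice}"
        )
    seed_region = next(r for r in regions if r.label == seed_label)

    records: dict[int, tuple[Region, int]] = {
        seed.seed_slice: (seed_region, seed_label)
    }
    footprints: dict[int, np.ndarray] = {seed.seed_slice: labeled == seed_label}

    for direction in (+1, -1):
        z = seed.seed_slice
        prev_region, _ = records[z]
        prev_fp = footprints[z]
        while True:
            z_next = z + direction
            if z_next < lo or z_next > hi:
                break
            nxt_labeled, nxt_regions = label_regions(mask[z_next])
            successor = _select_successor(
                nxt_labeled, nxt_regions, prev_fp, prev_region.area, prev_region.centroid
            )
            if successor is None:
                warnings.warn(
                    f"tracking truncated at slice {z_next}: no region overlaps "
                    "the previous footprint",
                    stacklevel=2,
                )
                break
            records[z_next] = (successor, successor.label)
            prev_fp = nxt_labeled == successor.label
            footprints[z_next] = prev_fp
            prev_region = successor
            z = z_next

    slices = sorted(records)
    points = np.array(
        [[records[z][0].centroid[0], records[z][0].centroid[1], z] for z in slices]
    )
    areas = np.array([records[z][0].area for z in slices])
    return Centerline(points=points, voxel_size_um=voxel_size_um, areas_px=areas)


def extract_bone_mask(mask: np.ndarray, centerline: Centerline, seed: SeedAnnotation) -> np.ndarray:
    """Return a mask containing only the tracked bone's voxels.

    Re-resolves the tracked region on each centerline slice from the
    stored center; useful for exporting the isolated bone.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for x, y, z in centerline.points:
        zi = int(z)
        labeled, _ = label_regions(mask[zi])
        lab = labeled[int(round(y)), int(round(x))]
        if lab == 0:  # center of mass can fall in the marrow cavity
            fg = np.argwhere(labeled > 0)
            if len(fg) == 0:
                continue
            d2 = (fg[:, 0] - y) ** 2 + (fg[:, 1] - x) ** 2
            nearest = fg[np.argmin(d2)]
            lab = labeled[nearest[0], nearest[1]]
        out[zi] = labeled == lab
    return out
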