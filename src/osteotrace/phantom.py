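"""Synthetic μCT phantoms of tubular bones with fully known geometry.

A phantom is a tube of cortical "bone" (bright ring) around a "marrow"
cavity, embedded in dark background, optionally next to a companion tube
with a diffuse soft-tissue bridge between them (the configuration that
defeats plain intensity thresholding on real paws).  The axis can be
straight, tilted, or gently curved; the inner and outer radii are linear
functions of the arc-length coordinate xi (mm above the nominal joint
slice), so the true cortical thickness gradient and thickness index are
known in closed form.

Voxelization uses the distance to the local tangent line of the axis at
each slice — exact for straight and tilted axes, and accurate to
O(curvature * r^2) for the curved preset — with 3x3 in-plane subpixel
area sampling so edges carry partial-volume fractions.  Degradation
(in-plane Gaussian blur, then additive Gaussian noise) is applied to the
grayscale stack only; the returned ground truth is never degraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .bone_tracker import DEFAULT_RANGE_MM, SeedAnnotation
from .texture_segmentation import DEFAULT_VOXEL_SIZE_UM, ImageStack

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "phantom_suite",
    "preset_spec",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic bone stack.

    Radii are linear in xi: r(xi) = r_joint + slope * xi, with xi the
    arc length (mm) along the axis above the joint slice.  The true
    thickness gradient is therefore r_out_slope - r_in_slope.
    Intensities are (background, soft_tissue, marrow, bone) in arbitrary
    units, ordered increasingly as in real μCT paw scans.
    """

    n_slices: int = 250
    slice_shape: tuple[int, int] = (72, 72)  # (ny, nx)
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    joint_z: int = 4
    center_xy: tuple[float, float] = (36.0, 36.0)  # axis position at the joint slice
    centerline_kind: str = "straight"  # straight | tilted | curved
    tilt_deg: float = 0.0
    curve_amplitude_px: float = 0.0
    curve_period_slices: float = 500.0
    r_out_joint_mm: float = 0.30
    r_out_slope: float = 0.0
    r_in_joint_mm: float = 0.18
    r_in_slope: float = 0.0
    intensities: tuple[float, float, float, float] = (20.0, 45.0, 70.0, 200.0)
    noise_sigma: float = 8.0
    blur_sigma: float = 0.8
    companion_offset_px: tuple[float, float] | None = None
    bridge: bool = False
    bridge_halfwidth_px: float = 7.0
    bridge_blur_px: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bg, soft, marrow, bone = self.intensities
        if not bg < soft < marrow < bone:
            raise ValueError(
                f"intensities must be ordered background < soft tissue < marrow "
                f"< bone, got {self.intensities}"
            )
        if self.centerline_kind not in ("straight", "tilted", "curved"):
            raise ValueError(f"unknown centerline kind {self.centerline_kind!r}")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom."""

    mask: np.ndarray  # (z, y, x) bool, bone voxels (all tubes)
    centerline: np.ndarray  # (n_slices, 3) x, y, z of the primary axis
    joint_z: int
    voxel_size_um: float
    r_in_joint_mm: float
    r_in_slope: float
    r_out_joint_mm: float
    r_out_slope: float
    ctg_true: float
    cti_true: float
    range_mm: tuple[float, float] = DEFAULT_RANGE_MM
    seed_annotation: SeedAnnotation | None = None

    def r_in_mm(self, xi: np.ndarray | float) -> np.ndarray | float:
        return self.r_in_joint_mm + self.r_in_slope * xi

    def r_out_mm(self, xi: np.ndarray | float) -> np.ndarray | float:
        return self.r_out_joint_mm + self.r_out_slope * xi


def _axis_centers(spec: PhantomSpec) -> np.ndarray:
    """In-plane axis position (cx, cy) per slice."""
    z = np.arange(spec.n_slices, dtype=float)
    cx0, cy0 = spec.center_xy
    cx = np.full_like(z, cx0)
    cy = np.full_like(z, cy0)
    if spec.centerline_kind == "tilted":
        cx = cx0 + np.tan(np.deg2rad(spec.tilt_deg)) * (z - spec.joint_z)
    elif spec.centerline_kind == "curved":
        cx = cx0 + spec.curve_amplitude_px * np.sin(
            2 * np.pi * (z - spec.joint_z) / spec.curve_period_slices
        )
    return np.column_stack([cx, cy, z])


def _axis_tangents(centers: np.ndarray) -> np.ndarray:
    """Unit tangent per slice from central differences of the axis."""
    grad = np.gradient(centers, axis=0)
    return grad / np.linalg.norm(grad, axis=1, keepdims=True)


def analytic_cti(
    truth_like: PhantomSpec | PhantomTruth, range_mm: tuple[float, float] = DEFAULT_RANGE_MM
) -> float:
    """Mean of (r_out - r_in)/r_out over the measurement range (trapezoid rule)."""
    xi = np.linspace(range_mm[0], range_mm[1], 2001)
    r_in = truth_like.r_in_joint_mm + truth_like.r_in_slope * xi
    r_out = truth_like.r_out_joint_mm + truth_like.r_out_slope * xi
    ratio = (r_out - r_in) / r_out
    return float(np.trapezoid(ratio, xi) / (range_mm[1] - range_mm[0]))


def generate_phantom(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Voxelize, degrade, and return (stack, truth); deterministic per seed."""
    ny, nx = spec.slice_shape
    voxel_mm = spec.voxel_size_um / 1000.0
    centers = _axis_centers(spec)
    tangents = _axis_tangents(centers)

    # arc length (mm) along the axis, zero at the joint slice
    steps = np.linalg.norm(np.diff(centers, axis=0), axis=1) * voxel_mm
    s = np.concatenate([[0.0], np.cumsum(steps)])
    s = s - s[spec.joint_z]

    xi_max = s[-1]
    r_in_end = spec.r_in_joint_mm + spec.r_in_slope * xi_max
    r_out_end = spec.r_out_joint_mm + spec.r_out_slope * xi_max
    # r_in == 0 everywhere means a solid rod (no marrow cavity)
    if min(spec.r_in_joint_mm, r_in_end) < 0:
        raise ValueError("r_in becomes negative within the stack")
    if min(spec.r_out_joint_mm - spec.r_in_joint_mm, r_out_end - r_in_end) <= 0:
        raise ValueError("cortical thickness must stay positive over the stack")

    all_centers = [centers]
    if spec.companion_offset_px is not None:
        offx, offy = spec.companion_offset_px
        shifted = centers.copy()
        shifted[:, 0] += offx
        shifted[:, 1] += offy
        all_centers.append(shifted)

    r_out_max_px = max(spec.r_out_joint_mm, r_out_end) / voxel_mm
    tz_min = tangents[:, 2].min()
    margin = r_out_max_px / tz_min + 1.5
    for cset in all_centers:
        if (
            cset[:, 0].min() - margin < 0
            or cset[:, 0].max() + margin > nx - 1
            or cset[:, 1].min() - margin < 0
            or cset[:, 1].max() + margin > ny - 1
        ):
            raise ValueError("tube geometry exits the volume; enlarge slice_shape")

    X, Y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    offsets = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
    bg, soft, marrow_i, bone_i = spec.intensities

    image = np.empty((spec.n_slices, ny, nx))
    mask = np.zeros((spec.n_slices, ny, nx), dtype=bool)

    for z in range(spec.n_slices):
        occ_bone = np.zeros((ny, nx))
        occ_marrow = np.zeros((ny, nx))
        for cset in all_centers:
            cx, cy, _ = cset[z]
            tx, ty, tz = tangents[z]
            for dx in offsets:
                for dy in offsets:
                    px = X + dx - cx
                    py = Y + dy - cy
                    a = px * tx + py * ty  # axial offset along the tangent
                    d2 = px**2 + py**2 - a**2
                    d = np.sqrt(np.maximum(d2, 0.0))
                    xi = s[z] + a * voxel_mm
                    r_in_px = (spec.r_in_joint_mm + spec.r_in_slope * xi) / voxel_mm
                    r_out_px = (spec.r_out_joint_mm + spec.r_out_slope * xi) / voxel_mm
                    occ_bone += (d >= r_in_px) & (d < r_out_px)
                    occ_marrow += d < r_in_px
        occ_bone /= 9.0
        occ_marrow /= 9.0
        occ_bone = np.clip(occ_bone, 0.0, 1.0)
        occ_marrow = np.clip(occ_marrow, 0.0, 1.0 - occ_bone)

        tissue = np.full((ny, nx), bg)
        if spec.bridge and spec.companion_offset_px is not None:
            tissue = tissue + (soft - bg) * _bridge_field(spec, all_centers, z, X, Y)
        image[z] = (
            tissue * (1.0 - occ_bone - occ_marrow)
            + marrow_i * occ_marrow
            + bone_i * occ_bone
        )
        mask[z] = occ_bone >= 0.5

    if spec.blur_sigma > 0:
        for z in range(spec.n_slices):
            image[z] = gaussian_filter(image[z], spec.blur_sigma)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    ctg_true = spec.r_out_slope - spec.r_in_slope
    truth = PhantomTruth(
        mask=mask,
        centerline=centers,
        joint_z=spec.joint_z,
        voxel_size_um=spec.voxel_size_um,
        r_in_joint_mm=spec.r_in_joint_mm,
        r_in_slope=spec.r_in_slope,
        r_out_joint_mm=spec.r_out_joint_mm,
        r_out_slope=spec.r_out_slope,
        ctg_true=ctg_true,
        cti_true=analytic_cti(spec),
        seed_annotation=_suggest_seed(spec, centers, s),
    )
    return ImageStack(voxels=image, voxel_size_um=spec.voxel_size_um), truth


def _bridge_field(
    spec: PhantomSpec,
    all_centers: list[np.ndarray],
    z: int,
    X: np.ndarray,
    Y: np.ndarray,
) -> np.ndarray:
    """Diffuse soft-tissue ridge between the two tube centers, in [0, 1].

    A hard capsule around the connecting segment is heavily smoothed so
    the bridge has weak gradients: bright enough to fool a global
    threshold, featureless enough to stay background under texture
    clustering.
    """
    (c1x, c1y, _), (c2x, c2y, _) = all_centers[0][z], all_centers[1][z]
    seg = np.array([c2x - c1x, c2y - c1y])
    seg_len2 = seg @ seg
    t = ((X - c1x) * seg[0] + (Y - c1y) * seg[1]) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dx = X - (c1x + t * seg[0])
    dy = Y - (c1y + t * seg[1])
    capsule = (np.hypot(dx, dy) < spec.bridge_halfwidth_px).astype(float)
    return gaussian_filter(capsule, spec.bridge_blur_px)


def _suggest_seed(
    spec: PhantomSpec, centers: np.ndarray, s: np.ndarray
) -> SeedAnnotation | None:
    """Seed annotation in the middle of the measurement window, on the ring."""
    voxel_mm = spec.voxel_size_um / 1000.0
    near, far = DEFAULT_RANGE_MM
    lo = spec.joint_z + int(np.ceil(near / voxel_mm))
    hi = spec.joint_z + int(np.floor(far / voxel_mm))
    hi = min(hi, spec.n_slices - 1)
    if lo > hi:
        mid = min(spec.joint_z + max((spec.n_slices - spec.joint_z) // 2, 1), spec.n_slices - 1)
    else:
        mid = (lo + hi) // 2
    xi = s[mid]
    r_mid_px = (
        (spec.r_in_joint_mm + spec.r_in_slope * xi)
        + (spec.r_out_joint_mm + spec.r_out_slope * xi)
    ) / 2.0 / voxel_mm
    cx, cy, _ = centers[mid]
    return SeedAnnotation(
        seed_slice=mid, seed_point=(cx, cy + r_mid_px), joint_z=spec.joint_z
    )


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

def _presets() -> dict[str, PhantomSpec]:
    base = PhantomSpec()
    tapered = {
        f"tapered_ctg{n}e-3": replace(
            base, r_in_slope=-n / 1000.0, rng_seed=20 + i
        )
        for i, n in enumerate((0, 5, 10, 15))
    }
    return {
        "straight_constant": replace(base, rng_seed=11),
        "tilted15": replace(
            base,
            centerline_kind="tilted",
            tilt_deg=15.0,
            slice_shape=(72, 152),
            center_xy=(28.0, 36.0),
            rng_seed=12,
        ),
        "tilted25": replace(
            base,
            centerline_kind="tilted",
            tilt_deg=25.0,
            slice_shape=(72, 200),
            center_xy=(28.0, 36.0),
            rng_seed=13,
        ),
        "curved": replace(
            base,
            centerline_kind="curved",
            curve_amplitude_px=8.0,
            curve_period_slices=500.0,
            slice_shape=(72, 96),
            center_xy=(44.0, 36.0),
            rng_seed=14,
        ),
        **tapered,
        "adjacent_bones_bridged": replace(
            base,
            n_slices=24,
            joint_z=0,
            slice_shape=(72, 124),
            center_xy=(34.0, 36.0),
            companion_offset_px=(54.0, 0.0),
            bridge=True,
            intensities=(20.0, 120.0, 140.0, 200.0),
            rng_seed=31,
        ),
    }


PRESET_NAMES: tuple[str, ...] = tuple(_presets())


def preset_spec(name: str) -> PhantomSpec:
    """The PhantomSpec of one named preset."""
    presets = _presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


def phantom_suite(names: tuple[str, ...] | None = None) -> list[tuple[str, PhantomSpec]]:
    """Stable, ordered list of (name, spec) for the named presets."""
    presets = _presets()
    if names is None:
        names = PRESET_NAMES
    return [(n, presets[n]) for n in names]
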