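"""Stack readers/writers, run configuration, and the batch pipeline.

Stacks are multi-page TIFFs or directories of numbered 2D TIFFs; the
isotropic voxel size comes from the caller or a YAML sidecar.  Integer
images are normalized by their dtype range so 8-bit, 16-bit and float
encodings of the same data segment identically downstream.

Outputs are tidy CSVs (one profile row per (xi, theta) ray; one metrics
row per bone) carrying the configuration hash and random seed for
provenance, ready for external mixed-model statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import filter_bank as fb
from .bone_tracker import DEFAULT_RANGE_MM, SeedAnnotation, track_bone
from .cortical_metrics import (
    DEFAULT_MIN_VALID_RAYS,
    DEFAULT_N_THETA,
    measure_bone,
)
from .texture_segmentation import DEFAULT_VOXEL_SIZE_UM, ImageStack, segment_stack

__all__ = [
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_mask",
    "read_seeds",
    "run_pipeline",
]

logger = logging.getLogger("osteotrace")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _check_keys(mapping: dict, allowed: set[str], block: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in config block {block!r}: {sorted(unknown)}")


@dataclass
class FiltersConfig:
    frequencies: tuple[float, ...] = fb.DEFAULT_FREQUENCIES
    orientations: tuple[float, ...] = fb.DEFAULT_ORIENTATIONS
    phases: tuple[float, ...] = fb.DEFAULT_PHASES
    dog_sigma_pairs: tuple[tuple[float, float], ...] = fb.DEFAULT_DOG_SIGMA_PAIRS
    base_support: int = fb.DEFAULT_BASE_SUPPORT

    def build(self) -> fb.FilterBank:
        return fb.build_bank(
            frequencies=self.frequencies,
            orientations=self.orientations,
            phases=self.phases,
            dog_sigma_pairs=tuple(tuple(p) for p in self.dog_sigma_pairs),
            base_support=self.base_support,
        )


@dataclass
class SegmentationConfig:
    seed: int = 0
    n_init: int = 10
    pooled: bool = False
    standardize: bool = False


@dataclass
class TrackingConfig:
    range_mm: tuple[float, float] = DEFAULT_RANGE_MM


@dataclass
class OrthoConfig:
    tangent_window: int = 5
    smooth_window: int = 5


@dataclass
class MetricsConfig:
    n_theta: int = DEFAULT_N_THETA
    min_valid_rays: int = DEFAULT_MIN_VALID_RAYS
    cti_variant: str = "radius"


@dataclass
class IOConfig:
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM


@dataclass
class RunConfig:
    """Validated configuration of the whole pipeline."""

    filters: FiltersConfig = field(default_factory=FiltersConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    ortho: OrthoConfig = field(default_factory=OrthoConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def __post_init__(self) -> None:
        near, far = self.tracking.range_mm
        if not 0 <= near < far:
            raise ValueError(f"invalid tracking range_mm {self.tracking.range_mm}")
        if self.metrics.n_theta < 4:
            raise ValueError(f"n_theta must be >= 4, got {self.metrics.n_theta}")
        if not 1 <= self.metrics.min_valid_rays <= self.metrics.n_theta:
            raise ValueError("min_valid_rays must be within [1, n_theta]")
        if self.metrics.cti_variant not in ("radius", "diameter"):
            raise ValueError(f"unknown cti_variant {self.metrics.cti_variant!r}")
        if self.io.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        if self.ortho.tangent_window < 1 or self.ortho.smooth_window < 1:
            raise ValueError("ortho windows must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "RunConfig":
        blocks = {
            "filters": FiltersConfig,
            "segmentation": SegmentationConfig,
            "tracking": TrackingConfig,
            "ortho": OrthoConfig,
            "metrics": MetricsConfig,
            "io": IOConfig,
        }
        _check_keys(raw, set(blocks), "<root>")
        kwargs = {}
        for name, cls_ in blocks.items():
            block = raw.get(name, {})
            allowed = {f.name for f in dataclasses.fields(cls_)}
            _check_keys(block, allowed, name)
            coerced = {}
            for key, value in block.items():
                if isinstance(value, list):
                    value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
                coerced[key] = value
            kwargs[name] = cls_(**coerced)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Stack IO
# ---------------------------------------------------------------------------

def _normalize_dtype(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    return arr.astype(float)


def _sidecar_voxel_size(path: Path) -> float | None:
    candidates = [path.with_suffix(".yaml")]
    if path.is_dir():
        candidates = [path / "voxel_size.yaml", path.with_suffix(".yaml")]
    for cand in candidates:
        if cand.is_file():
            meta = yaml.safe_load(cand.read_text()) or {}
            if "voxel_size_um" in meta:
                return float(meta["voxel_size_um"])
    return None


def read_stack(path: str | Path, voxel_size_um: float | None = None) -> ImageStack:
    """Load a multi-page TIFF or a sorted directory of 2D TIFF slices.

    Integer data are normalized by the dtype maximum.  The voxel size is
    taken from the argument, else from a YAML sidecar
    (``<stack>.yaml`` or ``<dir>/voxel_size.yaml`` with key
    ``voxel_size_um``); a missing voxel size is an error.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = []
        shape = None
        for f in files:
            img = tifffile.imread(f)
            if img.ndim != 2:
                raise ValueError(f"slice file {f.name} is not a single 2D image")
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"slice {f.name} has shape {img.shape}, expected {shape}"
                )
            slices.append(img)
        volume = np.stack(slices)
    elif path.is_file():
        volume = tifffile.imread(path)
        if volume.ndim == 2:
            volume = volume[None]
        if volume.ndim != 3:
            raise ValueError(f"{path} does not contain a 2D/3D TIFF stack")
    else:
        raise FileNotFoundError(str(path))

    if voxel_size_um is None:
        voxel_size_um = _sidecar_voxel_size(path)
    if voxel_size_um is None:
        raise ValueError(
            f"voxel size unknown for {path}: pass voxel_size_um or provide a "
            "YAML sidecar with key 'voxel_size_um'"
        )
    return ImageStack(voxels=_normalize_dtype(volume), voxel_size_um=voxel_size_um)


def write_stack(path: str | Path, volume: np.ndarray) -> None:
    """Write a volume as a multi-page TIFF, preserving its dtype."""
    tifffile.imwrite(Path(path), np.asarray(volume), photometric="minisblack")


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean volume as a 0/255 uint8 multi-page TIFF."""
    tifffile.imwrite(
        Path(path),
        np.asarray(mask, dtype=bool) * np.uint8(255),
        photometric="minisblack",
    )


def read_seeds(path: str | Path) -> list[tuple[str, SeedAnnotation]]:
    """Read per-bone seed annotations from a YAML list.

    Each record: ``{bone_id, seed_slice, x, y, joint_z}`` (bone_id
    optional; defaults to ``bone<i>``).
    """
    records = yaml.safe_load(Path(path).read_text())
    if not isinstance(records, list):
        raise ValueError(f"{path}: expected a YAML list of seed records")
    seeds = []
    for i, rec in enumerate(records):
        _check_keys(rec, {"bone_id", "stack_id", "seed_slice", "x", "y", "joint_z"}, f"seed[{i}]")
        bone_id = str(rec.get("bone_id", f"bone{i}"))
        seeds.append(
            (
                bone_id,
                SeedAnnotation(
                    seed_slice=int(rec["seed_slice"]),
                    seed_point=(float(rec["x"]), float(rec["y"])),
                    joint_z=int(rec["joint_z"]),
                ),
            )
        )
    return seeds


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    stack: ImageStack,
    seeds: list[tuple[str, SeedAnnotation]],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Segment -> track -> orthogonalize -> measure for every seeded bone.

    A precomputed ``mask`` skips segmentation.  Per-bone failures are
    logged and recorded without aborting the batch.  If ``out_dir`` is
    given, writes ``mask.tif``, per-bone ``profile_<id>.csv`` and the
    combined ``metrics.csv``; all CSVs carry the config hash and
    segmentation seed.  Returns the metrics table.
    """
    config = config or RunConfig()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    if mask is None:
        logger.info("segmenting %d slices", stack.n_slices)
        bank = config.filters.build()
        mask = segment_stack(
            stack,
            bank,
            seed=config.segmentation.seed,
            pooled=config.segmentation.pooled,
            standardize=config.segmentation.standardize,
        )
        if out_dir is not None:
            write_mask(out_dir / "mask.tif", mask)

    rows = []
    for bone_id, seed in seeds:
        try:
            metrics, profile = measure_bone(
                mask,
                seed,
                voxel_size_um=stack.voxel_size_um,
                range_mm=config.tracking.range_mm,
                n_theta=config.metrics.n_theta,
                min_valid_rays=config.metrics.min_valid_rays,
                tangent_window=config.ortho.tangent_window,
                smooth_window=config.ortho.smooth_window,
                cti_variant=config.metrics.cti_variant,
            )
        except ValueError as exc:
            logger.error("bone %s failed: %s", bone_id, exc)
            rows.append({"bone_id": bone_id, "error": str(exc)})
            continue
        rows.append(
            {
                "bone_id": bone_id,
                "ctg": metrics.ctg,
                "intercept_mm": metrics.intercept_mm,
                "cti": metrics.cti,
                "n_slices": metrics.n_slices,
                "fit_rms_mm": metrics.fit_rms_mm,
                "config_hash": config.config_hash,
                "kmeans_seed": config.segmentation.seed,
            }
        )
        if out_dir is not None:
            prof = profile_frame(profile)
            prof["config_hash"] = config.config_hash
            prof["kmeans_seed"] = config.segmentation.seed
            prof.to_csv(out_dir / f"profile_{bone_id}.csv", index=False)

    table = pd.DataFrame(rows)
    if out_dir is not None:
        table.to_csv(out_dir / "metrics.csv", index=False)
    return table


def profile_frame(profile) -> pd.DataFrame:
    """Long-format table of a ThicknessProfile: one row per (xi, theta) ray."""
    n_xi, n_theta = profile.r_in.shape
    xi = np.repeat(profile.xi, n_theta)
    theta = np.tile(profile.theta, n_xi)
    return pd.DataFrame(
        {
            "xi_mm": xi,
            "theta_rad": theta,
            "r_in_mm": profile.r_in.ravel(),
            "r_out_mm": profile.r_out.ravel(),
            "psi_mm": (profile.r_out - profile.r_in).ravel(),
            "valid": profile.valid.ravel(),
        }
    )
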