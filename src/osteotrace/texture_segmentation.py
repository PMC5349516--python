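"""Texture-based bone segmentation of μCT slices.

Each grayscale slice is convolved with the full filter bank (in the
Fourier domain, with mirror padding), giving every pixel an N_F-dimensional
feature vector of filter responses.  The pixels of a slice are then split
into two clusters with k-means++ (k = 2, Euclidean distance on the raw
responses) and the cluster whose members have the higher mean original
intensity is labeled bone.

Because the kernels are DC-free, the features — and therefore the
segmentation — are invariant to affine rescaling of the slice intensities,
which is what lets the method run on new scans without threshold tuning.
A conventional global-threshold + morphological-opening segmenter is
included as a baseline, along with the Dice overlap coefficient used to
compare segmentations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening
from sklearn.cluster import KMeans

from .filter_bank import FilterBank, build_bank

__all__ = [
    "ImageStack",
    "filter_responses",
    "kmeans_segment",
    "segment_stack",
    "baseline_threshold_segment",
    "dice",
    "DEFAULT_VOXEL_SIZE_UM",
]

#: Isotropic voxel edge length of the scans this pipeline targets (μm).
DEFAULT_VOXEL_SIZE_UM: float = 14.599


@dataclass
class ImageStack:
    """A 3D grayscale stack: ``voxels[z, y, x]`` with isotropic voxels."""

    voxels: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D stack, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack contains non-finite voxels")
        if self.voxel_size_um <= 0:
            raise ValueError(f"voxel size must be positive, got {self.voxel_size_um}")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0


def _fft_convolve_bank(padded: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Convolve one padded image with every kernel via a shared image FFT.

    Returns responses with the same shape as ``padded`` (one per kernel,
    stacked along the last axis).  Kernels are embedded centered at the
    origin of the FFT grid so the product implements true convolution
    with the kernel center on the output pixel.
    """
    shape = padded.shape
    img_f = np.fft.rfft2(padded)
    out = np.empty(shape + (bank.n_filters,), dtype=float)
    for idx, kernel in enumerate(bank):
        k = kernel.values
        kh, kw = k.shape
        if kh > shape[0] or kw > shape[1]:
            raise ValueError(
                f"kernel support {k.shape} exceeds padded slice {shape}"
            )
        embedded = np.zeros(shape)
        embedded[:kh, :kw] = k
        # Shift the kernel center to index (0, 0).
        embedded = np.roll(embedded, (-(kh // 2), -(kw // 2)), axis=(0, 1))
        out[..., idx] = np.fft.irfft2(img_f * np.fft.rfft2(embedded), s=shape)
    return out


def filter_responses(slice2d: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Per-pixel responses of one slice to every kernel in the bank.

    The slice is mirror-padded by half the largest kernel support before
    the Fourier-domain convolution, then cropped, so boundary responses
    see reflected image content instead of wrap-around.

    Returns an ``(M, N, N_F)`` array.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    if slice2d.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {slice2d.shape}")
    pad = bank.max_support // 2
    padded = np.pad(slice2d, pad, mode="symmetric")
    responses = _fft_convolve_bank(padded, bank)
    if pad:
        responses = responses[pad:-pad, pad:-pad]
    return responses


def kmeans_segment(
    features: np.ndarray,
    intensity: np.ndarray,
    seed: int = 0,
    n_init: int = 10,
    standardize: bool = False,
) -> np.ndarray:
    """Two-cluster k-means++ segmentation of one slice's feature stack.

    Parameters
    ----------
    features : (M, N, N_F) filter responses of the slice.
    intensity : (M, N) original grayscale slice; the cluster with the
        higher mean original intensity is labeled bone (bone is the
        radiodense phase).
    seed : RNG seed for the k-means++ initialization (10 restarts, best
        inertia kept).
    standardize : z-score each feature before clustering.  Off by
        default: distances are taken on the raw responses.

    Returns a boolean (M, N) bone mask.
    """
    features = np.asarray(features, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    m, n = intensity.shape
    flat = features.reshape(m * n, -1)
    if not np.all(np.isfinite(flat)):
        raise ValueError("non-finite filter responses")
    if np.all(flat == flat[0]):
        warnings.warn(
            "all feature vectors identical; degenerate clustering, "
            "returning all-background mask",
            stacklevel=2,
        )
        return np.zeros((m, n), dtype=bool)
    if standardize:
        std = flat.std(axis=0)
        std[std == 0] = 1.0
        flat = (flat - flat.mean(axis=0)) / std
    km = KMeans(n_clusters=2, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(flat).reshape(m, n)
    mean0 = intensity[labels == 0].mean()
    mean1 = intensity[labels == 1].mean()
    bone_label = int(mean1 > mean0)
    return labels == bone_label


def segment_stack(
    stack: ImageStack,
    bank: FilterBank | None = None,
    seed: int = 0,
    pooled: bool = False,
    standardize: bool = False,
    slice_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Texture-segment a whole stack into a boolean bone mask.

    By default each slice is clustered independently with the same seed,
    which keeps slices reproducible in isolation; ``pooled=True``
    clusters the pixels of all (selected) slices jointly instead.
    ``slice_indices`` restricts segmentation to a subset of slices
    (other slices come back all-background).
    """
    if bank is None:
        bank = build_bank()
    mask = np.zeros(stack.voxels.shape, dtype=bool)
    indices = (
        np.arange(stack.n_slices) if slice_indices is None else np.asarray(slice_indices)
    )
    if pooled:
        feats = []
        for z in indices:
            feats.append(filter_responses(stack.voxels[z], bank))
        m, n = stack.slice_shape
        flat = np.concatenate([f.reshape(m * n, -1) for f in feats])
        intensity = stack.voxels[indices].reshape(len(indices) * m * n)
        pooled_mask = kmeans_segment(
            flat.reshape(len(indices) * m, n, -1),
            intensity.reshape(len(indices) * m, n),
            seed=seed,
            standardize=standardize,
        )
        mask[indices] = pooled_mask.reshape(len(indices), m, n)
        return mask
    for z in indices:
        try:
            feats = filter_responses(stack.voxels[z], bank)
            mask[z] = kmeans_segment(
                feats, stack.voxels[z], seed=seed, standardize=standardize
            )
        except ValueError as exc:
            raise ValueError(f"segmentation failed on slice {z}: {exc}") from exc
    return mask


def baseline_threshold_segment(
    slice2d: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    opening_radius: int = 2,
) -> np.ndarray:
    """Global threshold + morphological opening baseline segmenter.

    ``method`` is ``"otsu"`` (data-driven global threshold) or
    ``"fixed"`` (requires ``threshold``).  The binary image is opened
    with a disc structuring element of the given radius.
    """
    slice2d = np.asarray(slice2d, dtype=float)
    if method == "otsu":
        thr = threshold_otsu(slice2d)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed thresholding requires a threshold value")
        thr = threshold
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    fg = slice2d > thr
    if opening_radius > 0:
        fg = opening(fg, disk(opening_radius))
    return fg


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks count as 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / total
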