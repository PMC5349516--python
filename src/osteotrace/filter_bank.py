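"""Gabor / difference-of-Gaussians filter bank for texture segmentation.

The bank follows the classic receptive-field design used for texture
discrimination: quadrature pairs of oriented Gabor filters (even and odd
phase) at several spatial frequencies, plus a few isotropic
center-surround difference-of-Gaussians (DoG) filters.  With the default
configuration the bank holds 40 kernels: 36 Gabors spanning 3 spatial
frequencies, 6 orientations and 2 phases, followed by 4 DoGs with a
positive center.

All kernels are made DC-free (zero mean) so that constant image regions
produce zero response, and the Gabors are L2-normalized so that all
oriented filters respond on a comparable scale.  Both choices matter for
the downstream Euclidean k-means clustering of pixel feature vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = [
    "GaborParams",
    "DoGParams",
    "Kernel",
    "FilterBank",
    "make_gabor",
    "make_dog",
    "build_bank",
    "DEFAULT_DOG_SIGMA_PAIRS",
    "DEFAULT_ORIENTATIONS",
    "DEFAULT_PHASES",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_BASE_SUPPORT",
]

#: DoG (center, surround) standard deviations as fractions of ``base_support``.
DEFAULT_DOG_SIGMA_PAIRS: tuple[tuple[float, float], ...] = (
    (0.075, 0.125),
    (0.125, 0.175),
    (0.175, 0.225),
    (0.225, 0.275),
)

#: Gabor orientations (radians): 6 directions uniformly covering the half circle.
DEFAULT_ORIENTATIONS: tuple[float, ...] = (
    0.0,
    np.pi / 6,
    np.pi / 3,
    np.pi / 2,
    2 * np.pi / 3,
    5 * np.pi / 6,
)

#: Gabor phases (radians): an even/odd quadrature pair.
DEFAULT_PHASES: tuple[float, float] = (0.0, np.pi / 2)

#: Gabor spatial frequencies (cycles/pixel), octave spaced.
DEFAULT_FREQUENCIES: tuple[float, ...] = (0.05, 0.1, 0.2)

#: Base support (pixels) that converts the dimensionless DoG sigma pairs
#: into pixel units.
DEFAULT_BASE_SUPPORT: int = 31


@dataclass(frozen=True)
class GaborParams:
    """Parameters of one Gabor kernel.

    omega: spatial frequency of the carrier sinusoid (cycles/pixel).
    theta: orientation of the carrier (radians).
    phi: phase of the carrier; 0 gives an even-symmetric kernel,
        pi/2 an odd-symmetric one.
    sigma: standard deviation of the isotropic Gaussian window (pixels).
        Window size is inversely proportional to frequency across the bank.
    """

    omega: float
    theta: float
    phi: float
    sigma: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"Gabor frequency must be positive, got {self.omega}")
        if self.sigma <= 0:
            raise ValueError(f"Gabor sigma must be positive, got {self.sigma}")


@dataclass(frozen=True)
class DoGParams:
    """Parameters of one difference-of-Gaussians kernel.

    sigma_center must be smaller than sigma_surround, which gives the
    kernel a positive center and a negative surround.
    """

    sigma_center: float
    sigma_surround: float

    def __post_init__(self) -> None:
        if not 0 < self.sigma_center:
            raise ValueError(f"DoG center sigma must be positive, got {self.sigma_center}")
        if self.sigma_center >= self.sigma_surround:
            raise ValueError(
                "DoG requires sigma_center < sigma_surround, got "
                f"{self.sigma_center} >= {self.sigma_surround}"
            )


@dataclass(frozen=True)
class Kernel:
    """A realized 2D filter kernel with its generating parameters."""

    values: np.ndarray
    params: Union[GaborParams, DoGParams]
    kind: str  # "gabor" | "dog"

    @property
    def support(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FilterBank:
    """Ordered, deterministic collection of texture kernels."""

    kernels: tuple[Kernel, ...] = field(default_factory=tuple)

    @property
    def n_filters(self) -> int:
        return len(self.kernels)

    @property
    def max_support(self) -> int:
        return max(k.support for k in self.kernels)

    def __iter__(self):
        return iter(self.kernels)

    def __len__(self) -> int:
        return len(self.kernels)

    def gallery(self, n_cols: int = 8) -> np.ndarray:
        """Tile all kernels into one image for visual inspection.

        Each kernel is rescaled to [0, 1] and padded to the largest
        support; useful for writing a quick PNG/TIFF of the bank.
        """
        side = self.max_support
        n = self.n_filters
        n_rows = int(np.ceil(n / n_cols))
        tile = np.zeros((n_rows * side, n_cols * side))
        for idx, kernel in enumerate(self.kernels):
            v = kernel.values
            lo, hi = v.min(), v.max()
            v = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
            r, c = divmod(idx, n_cols)
            off = (side - v.shape[0]) // 2
            tile[
                r * side + off : r * side + off + v.shape[0],
                c * side + off : c * side + off + v.shape[1],
            ] = v
        return tile


def _odd_support(minimum: float) -> int:
    s = int(np.ceil(minimum))
    return s + 1 if s % 2 == 0 else s


def _grid(support: int) -> tuple[np.ndarray, np.ndarray]:
    if support < 1 or support % 2 == 0:
        raise ValueError(f"kernel support must be odd and positive, got {support}")
    half = support // 2
    coords = np.arange(-half, half + 1, dtype=float)
    return np.meshgrid(coords, coords, indexing="xy")


def make_gabor(params: GaborParams, support: int | None = None) -> Kernel:
    """Realize a Gabor kernel: oriented sinusoid under an isotropic Gaussian.

    The kernel is evaluated on an odd square grid covering +-3 sigma by
    default, then mean-subtracted (DC-free) and L2-normalized.
    """
    if support is None:
        support = _odd_support(6 * params.sigma)
    x, y = _grid(support)
    # Rotate coordinates so the carrier oscillates along theta.
    x_rot = x * np.cos(params.theta) + y * np.sin(params.theta)
    envelope = np.exp(-(x**2 + y**2) / (2 * params.sigma**2))
    carrier = np.cos(2 * np.pi * params.omega * x_rot + params.phi)
    values = envelope * carrier
    values = values - values.mean()
    norm = np.linalg.norm(values)
    if norm == 0:
        raise ValueError(f"degenerate Gabor kernel for {params}")
    return Kernel(values=values / norm, params=params, kind="gabor")


def make_dog(params: DoGParams, support: int | None = None) -> Kernel:
    """Realize a DoG kernel: narrow minus wide Gaussian, both unit-sum.

    Discrete normalization of each Gaussian to unit sum makes the
    difference sum to zero exactly, independent of truncation.
    """
    if support is None:
        support = _odd_support(6 * params.sigma_surround)
    x, y = _grid(support)
    r2 = x**2 + y**2
    center = np.exp(-r2 / (2 * params.sigma_center**2))
    surround = np.exp(-r2 / (2 * params.sigma_surround**2))
    values = center / center.sum() - surround / surround.sum()
    return Kernel(values=values, params=params, kind="dog")


def gabor_sigma_constant(
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    dog_sigma_pairs: Sequence[tuple[float, float]] = DEFAULT_DOG_SIGMA_PAIRS,
    base_support: int = DEFAULT_BASE_SUPPORT,
) -> float:
    """Proportionality constant C with sigma_n = C / omega_n.

    Chosen so the widest Gabor window coincides with the widest DoG
    surround scale, tying the two kernel families to one scale range.
    """
    largest_dog = max(pair[1] for pair in dog_sigma_pairs) * base_support
    return largest_dog * min(frequencies)


def build_bank(
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES,
    orientations: Sequence[float] = DEFAULT_ORIENTATIONS,
    phases: Sequence[float] = DEFAULT_PHASES,
    dog_sigma_pairs: Sequence[tuple[float, float]] = DEFAULT_DOG_SIGMA_PAIRS,
    base_support: int = DEFAULT_BASE_SUPPORT,
) -> FilterBank:
    """Build the full texture bank: all Gabor combinations, then the DoGs.

    Ordering is deterministic: frequencies (outer) x orientations x
    phases (inner) for the Gabors, followed by the DoG pairs in the
    order given.  With defaults this yields 3*6*2 + 4 = 40 kernels.
    Duplicate parameter tuples are kept (the bank size is part of the
    contract) but trigger a warning.
    """
    sigma_const = gabor_sigma_constant(frequencies, dog_sigma_pairs, base_support)
    kernels: list[Kernel] = []
    seen: set = set()
    for omega in frequencies:
        for theta in orientations:
            for phi in phases:
                params = GaborParams(omega=omega, theta=theta, phi=phi, sigma=sigma_const / omega)
                key = ("gabor", omega, theta, phi)
                if key in seen:
                    warnings.warn(f"duplicate Gabor parameters {key}; kept", stacklevel=2)
                seen.add(key)
                kernels.append(make_gabor(params))
    for sig_c, sig_s in dog_sigma_pairs:
        params = DoGParams(
            sigma_center=sig_c * base_support, sigma_surround=sig_s * base_support
        )
        key = ("dog", sig_c, sig_s)
        if key in seen:
            warnings.warn(f"duplicate DoG parameters {key}; kept", stacklevel=2)
        seen.add(key)
        kernels.append(make_dog(params))
    return FilterBank(kernels=tuple(kernels))
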