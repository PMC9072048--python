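"""Raster types, image/config I/O, and the gray-level histogram.

Conventions used throughout the package:

* coordinates are ``(row, col)``, 0-based, row 0 at the top (raster order);
* gray levels are integers in ``[0, max_level]`` with ``max_level`` 255
  (8-bit) or 65535 (16-bit);
* feature/energy computations operate on intensities normalized to ``[0, 1]``
  by division by ``max_level``; mixture fitting operates on the integer
  gray-level histogram.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml

logger = logging.getLogger("curviseg")

__all__ = [
    "GrayImage",
    "Histogram",
    "RunConfig",
    "read_gray_image",
    "write_mask",
    "compute_histogram",
]

# ITU-R BT.601 luma coefficients, used only when explicit RGB conversion
# is requested.
_BT601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D single-channel image with a declared bit depth.

    Parameters
    ----------
    pixels : ndarray of int
        2-D array of gray levels, each in ``[0, max_level]``.
    bit_depth : int
        8 or 16.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < 3 or px.shape[1] < 3:
            raise ValueError(
                f"image must be at least 3x3 (Hessian filtering needs a "
                f"neighborhood), got {px.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(px.dtype, np.integer):
            if not np.all(px == np.round(px)):
                raise ValueError("pixel values must be integers")
            px = px.astype(np.uint16 if self.bit_depth == 16 else np.uint8)
        if px.min() < 0 or px.max() > self.max_level:
            raise ValueError(
                f"pixel values outside [0, {self.max_level}] for "
                f"{self.bit_depth}-bit image"
            )
        dtype = np.uint16 if self.bit_depth == 16 else np.uint8
        object.__setattr__(self, "pixels", px.astype(dtype, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def max_level(self) -> int:
        return (1 << self.bit_depth) - 1

    def normalized(self) -> np.ndarray:
        """Intensities scaled to ``[0, 1]`` as float64."""
        return self.pixels.astype(np.float64) / self.max_level


@dataclass(frozen=True)
class Histogram:
    """Gray-level histogram: ``counts[t]`` pixels at level ``t``."""

    counts: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or np.any(counts < 0):
            raise ValueError("counts must be a 1-D non-negative vector")
        if int(counts.sum()) != self.n_pixels:
            raise ValueError("sum(counts) must equal n_pixels")
        object.__setattr__(self, "counts", counts)

    @property
    def max_level(self) -> int:
        return len(self.counts) - 1

    @property
    def levels(self) -> np.ndarray:
        return np.arange(len(self.counts), dtype=np.float64)

    def mean(self) -> float:
        return float(np.sum(self.levels * self.counts) / self.n_pixels)

    def var(self) -> float:
        m = self.mean()
        return float(np.sum((self.levels - m) ** 2 * self.counts) / self.n_pixels)


def read_gray_image(path: str | Path, *, luminance: bool = False) -> GrayImage:
    """Read a single-channel PNG or TIFF as a :class:`GrayImage`.

    Multi-channel input is rejected unless ``luminance=True``, in which case
    the image is converted with BT.601 luma weights.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        n_ch = arr.shape[2]
        if not luminance:
            raise ValueError(
                f"image has {n_ch} channels; expected single-channel input "
                f"(pass luminance=True to convert with BT.601 weights)"
            )
        rgb = arr[..., :3].astype(np.float64)
        arr = np.round(rgb @ _BT601).astype(arr.dtype)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality: {arr.ndim}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype}; expected uint8/uint16")
    return GrayImage(arr, bit_depth=depth)


def write_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write a binary label field as an 8-bit PNG (background=0, feature=255)."""
    labels = np.asarray(labels)
    out = np.where(labels > 0, 255, 0).astype(np.uint8)
    iio.imwrite(Path(path), out)


def compute_histogram(img: GrayImage) -> Histogram:
    """Count pixels per gray level; length is ``max_level + 1``."""
    counts = np.bincount(img.pixels.ravel(), minlength=img.max_level + 1)
    return Histogram(counts=counts, n_pixels=img.height * img.width)


@dataclass
class RunConfig:
    """Resolved pipeline configuration.

    Attributes
    ----------
    n_background_gaussians : int
        Gaussian components modeling the background alongside the Rayleigh
        component (the mixture is 1 Rayleigh + this many Gaussians for the
        background plus 1 Gaussian for the bright target).
    em_tol : float
        Convergence threshold: RMSE of the stacked parameter vector between
        EM iterations.
    scales : tuple of float
        Strictly increasing scale grid (pixels) for the Hessian filter.
    beta : float
        Potts/MLL pairwise weight of the MRF prior.
    alpha : float
        Weight of the line-similarity mismatch term in the MRF energy.
    refine_r : float
        Manual scaling factor of the boundary-offset refinement; 0 disables.
    """

    n_background_gaussians: int = 2
    em_tol: float = 1e-6
    em_max_iter: int = 500
    scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    beta_r: float = 0.5
    c_r: float | None = None  # None -> per-scale adaptive (half max Frobenius norm)
    polarity: str = "bright"  # bright structures on dark background
    beta: float = 1.5
    alpha: float = 1.0
    icm_max_iter: int = 100
    refine_r: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        scales = tuple(float(s) for s in self.scales)
        if not scales or any(s <= 0 for s in scales):
            raise ValueError("scales must be non-empty and positive")
        if any(b >= a for b, a in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        if self.beta < 0 or self.alpha < 0 or self.refine_r < 0:
            raise ValueError("beta, alpha and refine_r must be non-negative")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")
        if self.em_max_iter < 1 or self.icm_max_iter < 1:
            raise ValueError("iteration caps must be >= 1")
        self.scales = scales

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in data:
            data["scales"] = tuple(data["scales"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(d["scales"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def log_resolved(self) -> None:
        """Echo the fully resolved configuration at INFO level."""
        logger.info("resolved config: %s", self.to_dict())
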