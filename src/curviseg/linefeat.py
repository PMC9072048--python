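"""Multiscale Hessian line-similarity (vesselness) filtering.

Second-order structure is measured by convolving the image with
scale-normalized Gaussian-derivative kernels; the Hessian eigenvalues then
feed a Frangi-style line-similarity measure, maximized over a scale grid so
that structures of different widths all respond strongly at their matching
scale.

The derivative kernels are sampled Gaussians corrected to be exact on
polynomials up to the derivative order (moment normalization), so a
quadratic image yields its analytic second derivatives to machine
precision away from the borders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import correlate1d

from .iohub import GrayImage

__all__ = [
    "HessianField",
    "FeatureMap",
    "hessian_at_scale",
    "eigvals2x2",
    "line_response",
    "multiscale_response",
]

GAMMA = 2.0  # scale-normalization exponent for second-order ridge detection
TRUNCATE = 4.0  # kernel support in units of s


@dataclass(frozen=True)
class HessianField:
    """Gamma-normalized second derivatives at one scale.

    ``lxx`` differentiates along columns (x = col), ``lyy`` along rows
    (y = row), ``lxy`` is the mixed derivative; one grid serves both
    off-diagonal entries of the symmetric Hessian.
    """

    lxx: np.ndarray
    lxy: np.ndarray
    lyy: np.ndarray
    scale: float


@dataclass(frozen=True)
class FeatureMap:
    """Multiscale line-similarity response in [0, 1] with, per pixel, the
    index of the scale attaining the maximum."""

    v: np.ndarray
    best_scale_idx: np.ndarray
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.v.shape != self.best_scale_idx.shape:
            raise ValueError("v and best_scale_idx must share a shape")
        if np.any(self.v < 0) or np.any(self.v > 1):
            raise ValueError("response must lie in [0, 1]")

    def to_tiff(self, path: str | Path) -> None:
        """Export the response as a 32-bit float TIFF for inspection."""
        import imageio.v3 as iio

        iio.imwrite(Path(path), self.v.astype(np.float32))


def _gauss_kernels(s: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled Gaussian kernel and its first/second derivatives, moment-
    corrected so that correlation reproduces derivatives of polynomials
    exactly (sum w = 0 and sum k^2 w = 2 for the second derivative, etc.)."""
    radius = int(TRUNCATE * s + 0.5)
    k = np.arange(-radius, radius + 1, dtype=np.float64)
    e = np.exp(-(k**2) / (2 * s * s))
    g = e / e.sum()
    d1 = -k / (s * s) * e
    d1 = d1 / np.sum(k * d1)
    d2 = (k**2 / s**4 - 1.0 / (s * s)) * e
    d2 = d2 - d2.mean()
    d2 = d2 * (2.0 / np.sum(k * k * d2))
    return g, d1, d2


def hessian_at_scale(img: GrayImage | np.ndarray, s: float) -> HessianField:
    """Gamma-normalized Hessian of the image at scale ``s``.

    Each component is the image convolved with the corresponding second
    derivative of a Gaussian of standard deviation ``s`` (separable kernels,
    reflective boundaries, truncated at ``4 s``), multiplied by ``s**GAMMA``.
    """
    if s <= 0:
        raise ValueError(f"scale must be positive, got {s}")
    arr = img.normalized() if isinstance(img, GrayImage) else np.asarray(img, float)
    g, d1, d2 = _gauss_kernels(s)
    norm = s**GAMMA

    def sep(row_k, col_k):
        tmp = correlate1d(arr, row_k, axis=0, mode="reflect")
        return correlate1d(tmp, col_k, axis=1, mode="reflect") * norm

    return HessianField(
        lxx=sep(g, d2), lxy=sep(d1, d1), lyy=sep(d2, g), scale=float(s)
    )


def eigvals2x2(lxx: float, lxy: float, lyy: float) -> tuple[float, float]:
    """Eigenvalues of the symmetric 2x2 matrix [[lxx, lxy], [lxy, lyy]],
    ordered by absolute value (|l1| <= |l2|); ties broken by signed value
    ascending."""
    half_tr = 0.5 * (lxx + lyy)
    disc = np.sqrt(0.25 * (lxx - lyy) ** 2 + lxy**2)
    a, b = half_tr - disc, half_tr + disc
    if abs(a) < abs(b):
        return float(a), float(b)
    if abs(b) < abs(a):
        return float(b), float(a)
    return (float(a), float(b)) if a <= b else (float(b), float(a))


def _eig_field(h: HessianField) -> tuple[np.ndarray, np.ndarray]:
    half_tr = 0.5 * (h.lxx + h.lyy)
    disc = np.sqrt(0.25 * (h.lxx - h.lyy) ** 2 + h.lxy**2)
    a, b = half_tr - disc, half_tr + disc  # a <= b always
    swap = np.abs(b) < np.abs(a)
    l1 = np.where(swap, b, a)
    l2 = np.where(swap, a, b)
    return l1, l2


def line_response(
    l1: float | np.ndarray,
    l2: float | np.ndarray,
    beta_r: float = 0.5,
    c_r: float = 1.0,
    polarity: str = "bright",
) -> float | np.ndarray:
    """Frangi 2-D line-similarity of a Hessian eigenvalue pair.

    For bright structures on a dark background the principal curvature
    across the line is strongly negative, so pixels with ``l2 >= 0`` are
    suppressed to 0; otherwise

    ``v = exp(-(l1/l2)**2 / (2 beta_r**2)) * (1 - exp(-(l1**2 + l2**2) / (2 c_r**2)))``

    The first factor penalizes blob-like isotropy, the second low overall
    second-order structure.  ``polarity='dark'`` flips the sign test.
    """
    if beta_r <= 0 or c_r <= 0:
        raise ValueError("beta_r and c_r must be positive")
    l1 = np.asarray(l1, dtype=np.float64)
    l2 = np.asarray(l2, dtype=np.float64)
    scalar = l1.ndim == 0
    l1, l2 = np.atleast_1d(l1), np.atleast_1d(l2)
    wrong_sign = l2 >= 0 if polarity == "bright" else l2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (l1 / np.where(l2 != 0, l2, 1.0)) ** 2, 0.0)
    s2 = l1**2 + l2**2
    v = np.exp(-rb2 / (2 * beta_r**2)) * (1.0 - np.exp(-s2 / (2 * c_r**2)))
    v = np.where(wrong_sign, 0.0, v)
    v = np.clip(v, 0.0, 1.0)
    return float(v[0]) if scalar else v


def multiscale_response(
    img: GrayImage | np.ndarray,
    scales: Sequence[float],
    beta_r: float = 0.5,
    c_r: float | None = None,
    polarity: str = "bright",
) -> FeatureMap:
    """Maximum line-similarity over a scale grid.

    When ``c_r`` is None it adapts per scale to half the maximum Frobenius
    norm of the Hessian over the image at that scale (a flat image then
    responds 0 everywhere).  ``best_scale_idx`` records the argmax, first
    index on ties.
    """
    scales = tuple(float(s) for s in scales)
    if not scales:
        raise ValueError("scale grid must be non-empty")
    if any(b >= a for b, a in zip(scales, scales[1:])):
        raise ValueError("scales must be strictly increasing")
    arr = img.normalized() if isinstance(img, GrayImage) else np.asarray(img, float)
    best_v = np.zeros(arr.shape)
    best_idx = np.zeros(arr.shape, dtype=np.int32)
    for i, s in enumerate(scales):
        h = hessian_at_scale(arr, s)
        l1, l2 = _eig_field(h)
        if c_r is None:
            frob = np.sqrt(h.lxx**2 + 2 * h.lxy**2 + h.lyy**2)
            c_s = 0.5 * float(frob.max())
            if c_s <= 0:
                continue  # no structure at this scale anywhere
        else:
            c_s = c_r
        v = line_response(l1, l2, beta_r=beta_r, c_r=c_s, polarity=polarity)
        better = v > best_v
        best_idx[better] = i
        best_v = np.where(better, v, best_v)
    return FeatureMap(v=best_v, best_scale_idx=best_idx, scales=scales)
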