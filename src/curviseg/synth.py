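"""Seeded curvilinear phantom generator with ground truth.

Phantoms emulate the statistical image model the pipeline assumes: a
tree-structured skeleton of smooth bright strokes of varying width
(random walk with angular jitter and binary branching), a background whose
gray levels follow a Rayleigh + two-Gaussian mixture, a Gaussian bright
target intensity, and additive zero-mean Gaussian noise whose variance is
specified on the [0, 1] normalized intensity scale so it is independent of
bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .iohub import GrayImage

__all__ = ["PhantomConfig", "PhantomPair", "generate_phantom", "add_gaussian_noise"]


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; defaults match the study conditions of the
    pipeline's evaluation (512x512 8-bit fields, a handful of branching
    strokes 2-6 px wide, well-separated background/target gray modes).

    ``angle_jitter=0`` together with ``branch_length`` produces exactly
    straight strokes of a known length; ``constant_background`` replaces
    the background mixture with a flat level — both exist for controlled
    experiments and tests.
    """

    height: int = 512
    width: int = 512
    n_branches: int = 4
    depth: int = 2
    width_range: tuple[int, int] = (2, 6)
    target_mean: float = 200.0
    target_sd: float = 12.0
    bg_rayleigh_sigma: float = 20.0
    bg_gauss_means: tuple[float, float] = (80.0, 120.0)
    bg_gauss_sds: tuple[float, float] = (12.0, 15.0)
    bg_weights: tuple[float, float, float] = (0.40, 0.35, 0.25)
    noise_variance: float = 0.0
    bit_depth: int = 8
    seed: int = 0
    angle_jitter: float = 0.15  # radians per unit step
    branch_length: int | None = None  # None -> random fraction of field size
    constant_background: int | None = None

    def __post_init__(self) -> None:
        if self.width_range[0] < 1 or self.width_range[0] > self.width_range[1]:
            raise ValueError("width_range must satisfy 1 <= w_min <= w_max")
        if self.target_sd <= 0 or any(s <= 0 for s in self.bg_gauss_sds):
            raise ValueError("all sds must be positive")
        if self.bg_rayleigh_sigma <= 0:
            raise ValueError("bg_rayleigh_sigma must be positive")
        if not np.isclose(sum(self.bg_weights), 1.0, atol=1e-9):
            raise ValueError("background component weights must sum to 1")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if self.height < 3 or self.width < 3:
            raise ValueError("field must be at least 3x3")


@dataclass(frozen=True)
class PhantomPair:
    image: GrayImage
    truth: np.ndarray  # uint8 label field, 1 = feature
    meta: dict

    def __post_init__(self) -> None:
        if self.image.shape != self.truth.shape:
            raise ValueError("image and truth shapes differ")


def _disk(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    if r < 1:
        return np.ones((1, 1), dtype=bool)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy * yy + xx * xx <= radius * radius + 1e-9


def _walk(rng, start, theta, length, jitter, H, W):
    """Unit-step random walk; returns visited integer pixels and the points
    where branches may sprout."""
    pts = []
    r, c = start
    for _ in range(int(length)):
        pr, pc = int(round(r)), int(round(c))
        if 0 <= pr < H and 0 <= pc < W:
            pts.append((pr, pc))
        elif pts:
            break  # walked off the field
        theta += rng.normal(0.0, jitter)
        r += np.sin(theta)
        c += np.cos(theta)
    return pts, theta


def _skeleton_tree(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Rasterized tree skeleton, dilated per branch to its sampled width."""
    H, W = cfg.height, cfg.width
    mask = np.zeros((H, W), dtype=bool)
    span = min(H, W)

    def draw_branch(start, theta, length, depth):
        pts, _ = _walk(rng, start, theta, length, cfg.angle_jitter, H, W)
        if not pts:
            return
        w = int(rng.integers(cfg.width_range[0], cfg.width_range[1] + 1))
        stroke = np.zeros((H, W), dtype=bool)
        idx = tuple(np.array(pts).T)
        stroke[idx] = True
        if w > 1:
            stroke = binary_dilation(stroke, structure=_disk((w - 1) / 2.0))
        mask[stroke] = True
        if depth > 0 and len(pts) > 4:
            # binary branching from a random interior point of the parent
            for sign in (-1.0, 1.0):
                j = int(rng.integers(len(pts) // 4, len(pts)))
                ang = theta + sign * rng.uniform(np.pi / 9, np.pi * 7 / 18)
                draw_branch(pts[j], ang, max(4, int(length * 0.6)), depth - 1)

    for _ in range(cfg.n_branches):
        start = (
            rng.uniform(0.15 * H, 0.85 * H),
            rng.uniform(0.15 * W, 0.85 * W),
        )
        theta = rng.uniform(0, 2 * np.pi)
        if cfg.branch_length is not None:
            length = cfg.branch_length
        else:
            length = rng.uniform(0.3, 0.6) * span
        draw_branch(start, theta, length, cfg.depth)
    return mask


def _quantize(arr: np.ndarray, max_level: int) -> np.ndarray:
    """Clip to range and round half-up to integer gray levels."""
    clipped = np.clip(arr, 0, max_level)
    return np.floor(clipped + 0.5).astype(np.uint16 if max_level > 255 else np.uint8)


def generate_phantom(cfg: PhantomConfig) -> PhantomPair:
    """Generate one phantom: skeleton tree -> truth mask -> gray sampling
    -> noise -> quantization.  Deterministic given the config (seed
    included).  If the drawn tree leaves the field empty, regeneration is
    retried with a perturbed seed up to 5 times."""
    max_level = (1 << cfg.bit_depth) - 1
    for attempt in range(5):
        seed = cfg.seed + attempt * 1_000_003
        ss = np.random.SeedSequence(seed)
        rng_tree, rng_bg, rng_fg, rng_noise = [
            np.random.default_rng(s) for s in ss.spawn(4)
        ]
        truth = _skeleton_tree(cfg, rng_tree)
        frac = truth.mean()
        if 0 < frac < 0.5:
            break
    else:
        raise RuntimeError("could not generate a non-empty phantom in 5 attempts")

    H, W = cfg.height, cfg.width
    if cfg.constant_background is not None:
        bg = np.full((H, W), float(cfg.constant_background))
    else:
        comp = rng_bg.choice(3, size=(H, W), p=cfg.bg_weights)
        bg = np.empty((H, W))
        bg[comp == 0] = rng_bg.rayleigh(cfg.bg_rayleigh_sigma, int((comp == 0).sum()))
        for j in (0, 1):
            m = comp == j + 1
            bg[m] = rng_bg.normal(cfg.bg_gauss_means[j], cfg.bg_gauss_sds[j], int(m.sum()))
    fg = rng_fg.normal(cfg.target_mean, cfg.target_sd, size=(H, W))
    clean = np.where(truth, fg, bg)
    img = GrayImage(_quantize(clean, max_level), bit_depth=cfg.bit_depth)
    if cfg.noise_variance > 0:
        img = add_gaussian_noise(img, cfg.noise_variance, rng=rng_noise)
    meta = asdict(cfg)
    meta["attempt_seed"] = seed
    meta["foreground_fraction"] = float(frac)
    return PhantomPair(image=img, truth=truth.astype(np.uint8), meta=meta)


def add_gaussian_noise(
    img: GrayImage,
    variance: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> GrayImage:
    """Add i.i.d. zero-mean Gaussian noise of the given variance on the
    normalized [0, 1] scale, then clip and re-quantize to the image's bit
    depth.  Variance 0 returns the input unchanged."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return img
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = img.normalized() + rng.normal(0.0, np.sqrt(variance), size=img.shape)
    levels = _quantize(np.clip(noisy, 0.0, 1.0) * img.max_level, img.max_level)
    return GrayImage(levels, bit_depth=img.bit_depth)
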