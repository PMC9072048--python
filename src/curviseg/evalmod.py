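"""Segmentation metrics, the K-means gray-level baseline, and the
noise-robustness experiment harness.

The headline ratio ``pr_ratio = T / (T + F)`` with T = correct calls
(tp + tn) and F = false calls (fp + fn) coincides with pixel accuracy; it
is reported under both names so either convention can be traced in the
output.  Segmentation error is defined as ``1 - accuracy``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .iohub import GrayImage, RunConfig, compute_histogram
from .synth import PhantomConfig, generate_phantom

__all__ = [
    "ConfusionTable",
    "MetricReport",
    "confusion_metrics",
    "kmeans_gray",
    "noise_robustness",
    "RobustnessResult",
]


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Pixel-level metrics; a ratio with an empty denominator is reported
    as None (undefined), never as NaN."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    pr_ratio: float
    iou_bg: float | None
    iou_fg: float | None
    miou: float | None
    confusion: ConfusionTable

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "pr_ratio": self.pr_ratio,
            "iou_bg": self.iou_bg,
            "iou_fg": self.iou_fg,
            "miou": self.miou,
            "tp": self.confusion.tp,
            "fp": self.confusion.fp,
            "tn": self.confusion.tn,
            "fn": self.confusion.fn,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """Confusion-matrix metrics of a binary prediction against truth.

    Foreground (label 1) is the positive class.  ``pr_ratio`` is
    T/(T+F) with T = tp+tn, F = fp+fn, i.e. identical to accuracy.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    tn = int(np.count_nonzero(~p & ~t))
    fn = int(np.count_nonzero(~p & t))
    n = tp + fp + tn + fn
    iou_fg = _ratio(tp, tp + fp + fn)
    iou_bg = _ratio(tn, tn + fn + fp)
    miou = (iou_bg + iou_fg) / 2 if iou_bg is not None and iou_fg is not None else None
    acc = (tp + tn) / n
    return MetricReport(
        accuracy=acc,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        pr_ratio=acc,
        iou_bg=iou_bg,
        iou_fg=iou_fg,
        miou=miou,
        confusion=ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn),
    )


def kmeans_gray(img: GrayImage, seed: int = 0) -> np.ndarray:
    """Two-cluster Lloyd's algorithm on the gray histogram.

    Centroids start at the 25th/75th percentile gray levels (deterministic;
    ``seed`` is accepted for interface symmetry and recorded provenance but
    the initialization consumes no randomness).  Gray levels are assigned
    to the nearer centroid, centroids updated as count-weighted means,
    iterated to an assignment fixed point.  The cluster with the higher
    mean becomes the feature class.
    """
    hist = compute_histogram(img)
    nz = np.nonzero(hist.counts)[0]
    if len(nz) < 2:
        raise ValueError("constant image: K-means needs >= 2 distinct gray levels")
    cum = np.cumsum(hist.counts)
    # first level strictly above the quantile mass (right-sided quantile)
    c0 = float(np.searchsorted(cum, 0.25 * hist.n_pixels, side="right"))
    c1 = float(np.searchsorted(cum, 0.75 * hist.n_pixels, side="right"))
    if c0 == c1:
        c0, c1 = float(nz[0]), float(nz[-1])
    t = hist.levels
    h = hist.counts.astype(float)
    assign = None
    for _ in range(1000):
        new_assign = np.abs(t - c0) > np.abs(t - c1)  # True -> cluster 1
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for which, sel in ((0, ~assign), (1, assign)):
            mass = h[sel].sum()
            if mass > 0:
                m = float(np.sum(t[sel] * h[sel]) / mass)
                if which == 0:
                    c0 = m
                else:
                    c1 = m
    feature_is_1 = c1 >= c0
    lut = assign if feature_is_1 else ~assign
    return lut.astype(np.uint8)[img.pixels]


@dataclass(frozen=True)
class RobustnessResult:
    """Noise-robustness table: one summary row per variance plus the full
    per-(variance, seed) run log for provenance."""

    summary: pd.DataFrame  # columns: variance, mean_error, sd_error
    runs: pd.DataFrame  # columns: variance, seed, error, accuracy


def noise_robustness(
    cfg: PhantomConfig,
    variances: Sequence[float],
    n_seeds: int,
    pipeline: RunConfig | None = None,
) -> RobustnessResult:
    """Segmentation error (1 - accuracy) of the full pipeline across noise
    levels: for each variance, ``n_seeds`` phantoms are generated (seeds
    ``cfg.seed .. cfg.seed + n_seeds - 1``), segmented, and scored against
    their ground truth."""
    from .model import CurvilinearModel  # local import: avoid cycle

    if not variances:
        raise ValueError("variances must be non-empty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    pipeline = pipeline or RunConfig()
    rows = []
    for var in variances:
        for k in range(n_seeds):
            pcfg = PhantomConfig(
                **{**cfg.__dict__, "noise_variance": float(var), "seed": cfg.seed + k}
            )
            pair = generate_phantom(pcfg)
            res = CurvilinearModel(pair.image, config=pipeline).fit()
            rep = confusion_metrics(res.labels, pair.truth)
            rows.append(
                {
                    "variance": float(var),
                    "seed": pcfg.seed,
                    "error": 1.0 - rep.accuracy,
                    "accuracy": rep.accuracy,
                }
            )
    runs = pd.DataFrame(rows)
    summary = (
        runs.groupby("variance", sort=False)["error"]
        .agg(mean_error="mean", sd_error="std")
        .reset_index()
        .fillna({"sd_error": 0.0})
    )
    return RobustnessResult(summary=summary, runs=runs)
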