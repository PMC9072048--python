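"""Model/Results front end for the full segmentation pipeline.

``CurvilinearModel`` holds an observed grayscale image and a resolved
configuration; ``fit()`` runs the four stages — histogram EM on the gray
mixture, multiscale Hessian line filtering, MRF/ICM labeling, and
boundary-offset refinement — and returns a ``CurvilinearResults`` object
carrying the label field, the fitted mixture with its likelihood trace,
the ICM energy trace, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import mrf, refine
from .evalmod import MetricReport, confusion_metrics
from .iohub import GrayImage, RunConfig, compute_histogram, read_gray_image, write_mask
from .linefeat import FeatureMap, multiscale_response
from .mixture import ComponentSpec, EMResult, fit_em, likelihood_energy

logger = logging.getLogger("curviseg")

__all__ = ["CurvilinearModel", "CurvilinearResults"]


class CurvilinearModel:
    """Segmentation model for bright curvilinear structures in a grayscale
    image.

    Parameters
    ----------
    image : GrayImage
        The observed image.
    config : RunConfig, optional
        Pipeline configuration; defaults are the package's documented
        defaults (1 Rayleigh + 2 background Gaussians + 1 target Gaussian,
        scale grid 1..8 px, beta=1.5, alpha=1.0, r=1.0).

    Examples
    --------
    >>> from curviseg import CurvilinearModel, generate_phantom, PhantomConfig
    >>> pair = generate_phantom(PhantomConfig(height=96, width=96, seed=7))
    >>> res = CurvilinearModel(pair.image).fit()
    >>> res.labels.shape
    (96, 96)
    """

    def __init__(self, image: GrayImage, config: RunConfig | None = None):
        if not isinstance(image, GrayImage):
            image = GrayImage(np.asarray(image))
        self.image = image
        self.config = config or RunConfig()

    @classmethod
    def from_file(
        cls,
        path: str | Path,
        config: RunConfig | None = None,
        luminance: bool = False,
    ) -> "CurvilinearModel":
        return cls(read_gray_image(path, luminance=luminance), config=config)

    def fit(self) -> "CurvilinearResults":
        cfg = self.config
        cfg.log_resolved()
        timings: dict[str, float] = {}

        t0 = time.perf_counter()
        hist = compute_histogram(self.image)
        spec = ComponentSpec(
            n_rayleigh=1,
            n_background_gaussians=cfg.n_background_gaussians,
            n_target_gaussians=1,
        )
        em = fit_em(hist, spec, tol=cfg.em_tol, max_iter=cfg.em_max_iter, seed=cfg.seed)
        timings["mixture_em"] = time.perf_counter() - t0
        logger.info(
            "EM: %d iterations, converged=%s, loglik=%.2f",
            em.n_iter, em.converged, em.loglik_trace[-1],
        )

        t0 = time.perf_counter()
        fmap = multiscale_response(
            self.image, cfg.scales, beta_r=cfg.beta_r, c_r=cfg.c_r, polarity=cfg.polarity
        )
        timings["line_features"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        energies = likelihood_energy(self.image, em.params)
        icm = mrf.icm_segment(
            energies, fmap, beta=cfg.beta, alpha=cfg.alpha, max_iter=cfg.icm_max_iter
        )
        timings["icm"] = time.perf_counter() - t0
        logger.info("ICM: %d sweeps, final energy %.2f", icm.n_sweeps, icm.energy_trace[-1])

        t0 = time.perf_counter()
        labels = icm.labels
        if cfg.refine_r > 0:
            bmap = refine.boundary_map(labels)
            dmap = refine.direction_map(labels, bmap)
            labels = refine.refine_labels(labels, bmap, dmap, r=cfg.refine_r)
        timings["refine"] = time.perf_counter() - t0
        for stage, dt in timings.items():
            logger.info("stage %-14s %.3f s", stage, dt)

        return CurvilinearResults(
            model=self, em=em, feature_map=fmap, icm=icm, labels=labels, timings=timings
        )


@dataclass(frozen=True)
class CurvilinearResults:
    """Fit results: final label field plus every stage's diagnostics."""

    model: CurvilinearModel
    em: EMResult
    feature_map: FeatureMap
    icm: mrf.ICMResult
    labels: np.ndarray
    timings: dict

    @property
    def mixture(self):
        return self.em.params

    @property
    def energy_trace(self) -> np.ndarray:
        return self.icm.energy_trace

    def evaluate(self, truth: np.ndarray) -> MetricReport:
        """Score the final labeling against a ground-truth mask."""
        return confusion_metrics(self.labels, truth)

    def save_mask(self, path: str | Path) -> None:
        write_mask(path, self.labels)

    def summary(self) -> str:
        p = self.mixture
        cfg = self.model.config
        lines = [
            "Curvilinear segmentation results",
            "=" * 56,
            f"image: {self.model.image.height} x {self.model.image.width}, "
            f"{self.model.image.bit_depth}-bit",
            f"foreground fraction: {float(np.mean(self.labels)):.4f}",
            "",
            "Gray mixture (histogram EM)",
            "-" * 56,
            f"{'component':<22}{'weight':>9}{'location':>12}{'spread':>10}",
        ]
        k = 0
        if p.has_rayleigh:
            lines.append(
                f"{'rayleigh (background)':<22}{p.weights[0]:>9.4f}"
                f"{p.rayleigh_sigma:>12.2f}{'':>10}"
            )
            k = 1
        for j, (mu, sd) in enumerate(zip(p.gauss_means, p.gauss_sds)):
            tag = p.classes[k + j]
            lines.append(
                f"{f'gaussian ({tag})':<22}{p.weights[k + j]:>9.4f}{mu:>12.2f}{sd:>10.2f}"
            )
        lines += [
            "",
            f"EM iterations: {self.em.n_iter} (converged: {self.em.converged}); "
            f"final log-likelihood: {self.em.loglik_trace[-1]:.2f}",
            f"ICM sweeps: {self.icm.n_sweeps}; "
            f"energy {self.energy_trace[0]:.2f} -> {self.energy_trace[-1]:.2f}",
            f"config: beta={cfg.beta}, alpha={cfg.alpha}, r={cfg.refine_r}, "
            f"scales={list(cfg.scales)}",
        ]
        return "\n".join(lines)

    def plot(self, truth: np.ndarray | None = None):
        """Quick-look figure: image, line-similarity response, labels, and
        (optionally) ground truth.  Returns the matplotlib Figure."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        n = 4 if truth is not None else 3
        fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.4))
        axes[0].imshow(self.model.image.pixels, cmap="gray")
        axes[0].set_title("image")
        axes[1].imshow(self.feature_map.v, cmap="magma", vmin=0, vmax=1)
        axes[1].set_title("line similarity")
        axes[2].imshow(self.labels, cmap="gray", vmin=0, vmax=1)
        axes[2].set_title("labels")
        if truth is not None:
            axes[3].imshow(truth, cmap="gray", vmin=0, vmax=1)
            axes[3].set_title("truth")
        for ax in axes:
            ax.axis("off")
        fig.tight_layout()
        return fig
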