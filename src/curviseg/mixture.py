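"""Finite Rayleigh+Gaussian mixture of the gray histogram, fit by EM.

The observed image is split into a background class — one Rayleigh component
for the dark/low-gray mass plus Gaussian components for mid-gray tissue —
and a bright target class modeled by a single Gaussian.  EM runs on the
gray-level histogram rather than per pixel: responsibilities are computed
once per gray level and weighted by the level's frequency, which makes each
iteration O(gray levels) instead of O(pixels) while producing identical
updates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .iohub import GrayImage, Histogram

logger = logging.getLogger("curviseg")

__all__ = [
    "ComponentSpec",
    "MixtureParams",
    "EnergyMapPair",
    "EMResult",
    "mixture_pdf",
    "fit_em",
    "likelihood_energy",
    "SD_FLOOR",
    "P_FLOOR",
    "E_MAX",
]

SD_FLOOR = 0.5  # gray levels; prevents singular likelihood spikes
P_FLOOR = 1e-12
E_MAX = -np.log(P_FLOOR)

BACKGROUND = "background"
TARGET = "target"


@dataclass(frozen=True)
class ComponentSpec:
    """Mixture composition: ``n_rayleigh`` Rayleigh components (0 or 1),
    ``n_background_gaussians`` Gaussians tagged background, and
    ``n_target_gaussians`` Gaussians tagged target (0 or 1).  The default
    is the full model: 1 Rayleigh + 2 background Gaussians + 1 target."""

    n_rayleigh: int = 1
    n_background_gaussians: int = 2
    n_target_gaussians: int = 1

    def __post_init__(self) -> None:
        if self.n_rayleigh not in (0, 1):
            raise ValueError("n_rayleigh must be 0 or 1")
        if self.n_target_gaussians not in (0, 1):
            raise ValueError("n_target_gaussians must be 0 or 1")
        if self.n_background_gaussians < 0:
            raise ValueError("n_background_gaussians must be >= 0")
        if self.n_components < 1:
            raise ValueError("at least one component required")

    @property
    def n_gaussians(self) -> int:
        return self.n_background_gaussians + self.n_target_gaussians

    @property
    def n_components(self) -> int:
        return self.n_rayleigh + self.n_gaussians


@dataclass(frozen=True)
class MixtureParams:
    """Fitted mixture parameters.

    Component order: the Rayleigh component first (if present), then
    Gaussians in increasing order of their initial location; the target
    Gaussian, if present, is the last component.  ``classes[k]`` is
    ``"background"`` or ``"target"`` per component.
    """

    weights: np.ndarray
    rayleigh_sigma: float | None
    gauss_means: np.ndarray
    gauss_sds: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        means = np.asarray(self.gauss_means, dtype=np.float64)
        sds = np.asarray(self.gauss_sds, dtype=np.float64)
        n_ray = 1 if self.rayleigh_sigma is not None else 0
        if len(w) != n_ray + len(means):
            raise ValueError("weights length must match component count")
        if len(means) != len(sds):
            raise ValueError("gauss_means and gauss_sds must align")
        if len(self.classes) != len(w):
            raise ValueError("classes must tag every component")
        if any(c not in (BACKGROUND, TARGET) for c in self.classes):
            raise ValueError("classes must be 'background' or 'target'")
        if sum(c == TARGET for c in self.classes) > 1:
            raise ValueError("at most one target component")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights must sum to 1, got {w.sum()!r}")
        if np.any(w <= 0) or np.any(w >= 1 + 1e-12):
            raise ValueError("weights must lie in (0, 1)")
        if self.rayleigh_sigma is not None and self.rayleigh_sigma <= 0:
            raise ValueError("rayleigh_sigma must be positive")
        if np.any(sds < SD_FLOOR - 1e-12):
            raise ValueError(f"all sds must be >= {SD_FLOOR}")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "gauss_means", means)
        object.__setattr__(self, "gauss_sds", sds)
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def has_rayleigh(self) -> bool:
        return self.rayleigh_sigma is not None

    @property
    def target_index(self) -> int | None:
        for k, c in enumerate(self.classes):
            if c == TARGET:
                return k
        return None

    def component_densities(self, t: np.ndarray) -> np.ndarray:
        """Per-component densities at gray levels ``t``; shape (M, len(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=np.float64))
        out = np.empty((self.n_components, len(t)))
        k0 = 0
        if self.has_rayleigh:
            out[0] = _rayleigh_pdf(t, self.rayleigh_sigma)
            k0 = 1
        for j, (mu, sd) in enumerate(zip(self.gauss_means, self.gauss_sds)):
            out[k0 + j] = _gauss_pdf(t, mu, sd)
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "schema_version": 1,
            "weights": self.weights.tolist(),
            "rayleigh_sigma": self.rayleigh_sigma,
            "gauss_means": self.gauss_means.tolist(),
            "gauss_sds": self.gauss_sds.tolist(),
            "classes": list(self.classes),
        }
        Path(path).write_text(json.dumps(data, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "MixtureParams":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        if data.get("schema_version") != 1:
            raise ValueError("unsupported mixture schema version")
        return cls(
            weights=np.asarray(data["weights"]),
            rayleigh_sigma=data["rayleigh_sigma"],
            gauss_means=np.asarray(data["gauss_means"]),
            gauss_sds=np.asarray(data["gauss_sds"]),
            classes=tuple(data["classes"]),
        )


@dataclass(frozen=True)
class EnergyMapPair:
    """Negative log class-conditional likelihoods per pixel, clamped to
    ``[0, E_MAX]``."""

    e_bg: np.ndarray
    e_fg: np.ndarray

    def __post_init__(self) -> None:
        if self.e_bg.shape != self.e_fg.shape:
            raise ValueError("energy maps must share a shape")


@dataclass(frozen=True)
class EMResult:
    params: MixtureParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


def _rayleigh_pdf(t: np.ndarray, sigma: float) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    out = (t / sigma**2) * np.exp(-(t**2) / (2 * sigma**2))
    return np.where(t >= 0, out, 0.0)


def _gauss_pdf(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    return np.exp(-((t - mu) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi))


def mixture_pdf(t: float | np.ndarray, params: MixtureParams) -> float | np.ndarray:
    """Mixture density sum_k w_k f_k(t) at gray level(s) ``t``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    dens = params.component_densities(t_arr)
    out = params.weights @ dens
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def _stack_params(w, sigma_r, means, sds) -> np.ndarray:
    parts = [np.asarray(w, dtype=float)]
    if sigma_r is not None:
        parts.append(np.asarray([sigma_r], dtype=float))
    parts += [np.asarray(means, dtype=float), np.asarray(sds, dtype=float)]
    return np.concatenate(parts)


def _quantile_level(hist: Histogram, q: float) -> float:
    """Gray level at cumulative mass q (first level reaching it)."""
    cum = np.cumsum(hist.counts)
    idx = int(np.searchsorted(cum, q * hist.n_pixels, side="left"))
    return float(min(idx, hist.max_level))


def _init_params(hist: Histogram, spec: ComponentSpec, rng: np.random.Generator):
    """Seeded quantile initialization.

    The Rayleigh component starts from the mean of the lowest-quartile mass;
    Gaussians start at evenly spaced quantile levels of the full histogram
    (the target Gaussian takes the top slot), with a common sd from the
    global spread.
    """
    M = spec.n_components
    t = hist.levels
    # Rayleigh: fit to the lowest quartile by the mean relation E[t]=sigma*sqrt(pi/2)
    sigma_r = None
    if spec.n_rayleigh:
        q25 = _quantile_level(hist, 0.25)
        mask = t <= max(q25, 1.0)
        mass = hist.counts[mask.astype(bool)].sum()
        if mass > 0:
            m_low = float(np.sum(t[mask] * hist.counts[mask]) / mass)
        else:
            m_low = 1.0
        sigma_r = max(m_low / np.sqrt(np.pi / 2), 1.0)
    n_g = spec.n_gaussians
    sd0 = max(np.sqrt(hist.var()) / max(M, 1), SD_FLOOR)
    # Gaussian slots live above the Rayleigh's quartile so they start clear
    # of the low-gray mass the Rayleigh is meant to explain.  The target
    # component, when present, starts from the top-quantile mass: the bright
    # structure typically occupies a small fraction of the pixels, so an
    # evenly spaced slot would start it inside a background mode.
    q_lo = 0.25 if spec.n_rayleigh else 0.0
    n_bg = spec.n_background_gaussians
    qs = [q_lo + (0.95 - q_lo) * (j + 0.5) / max(n_bg, 1) for j in range(n_bg)]
    if spec.n_target_gaussians:
        qs.append(0.995)
    means = np.array([_quantile_level(hist, q) for q in qs], dtype=float)
    # jitter resolves coincident quantiles deterministically given the seed
    means = np.sort(means + rng.normal(0.0, 1e-3, size=n_g))
    sds = np.full(n_g, sd0)
    weights = np.full(M, 1.0 / M)
    return weights, sigma_r, means, sds


def fit_em(
    hist: Histogram,
    spec: ComponentSpec = ComponentSpec(),
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> EMResult:
    """Fit the mixture to a gray histogram by histogram-weighted EM.

    E-step: responsibilities per gray level, weighted by the level counts.
    M-step closed forms (stationarity of the expected complete-data
    log-likelihood):

    * ``w_k   = sum_t h_t r_kt / n``
    * ``mu_k  = sum_t h_t r_kt t / sum_t h_t r_kt`` and ``sd_k**2`` likewise
      for Gaussian components
    * ``sigma**2 = sum_t h_t r_t t**2 / (2 sum_t h_t r_t)`` for the Rayleigh

    Iterates until the RMSE of the stacked parameter vector between
    consecutive iterations drops below ``tol`` or ``max_iter`` is reached.

    Raises
    ------
    ValueError
        If the histogram is empty or concentrated on a single gray level
        (degenerate input: no mixture is identifiable).
    """
    if hist.n_pixels == 0:
        raise ValueError("empty histogram")
    if int(np.count_nonzero(hist.counts)) < 2:
        raise ValueError("degenerate histogram: all pixels share one gray level")
    rng = np.random.default_rng(seed)
    w, sigma_r, means, sds = _init_params(hist, spec, rng)

    t = hist.levels
    h = hist.counts.astype(np.float64)
    n = float(hist.n_pixels)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dens = _densities(t, sigma_r, means, sds)  # (M, T)
        weighted = w[:, None] * dens
        total = weighted.sum(axis=0)
        trace.append(float(np.sum(h * np.log(np.maximum(total, 1e-300)))))
        resp = weighted / np.maximum(total, 1e-300)[None, :]

        mass = resp @ h  # effective count per component
        collapsed = mass < 1e-8 * n
        if np.any(collapsed):
            warnings.warn(
                "mixture component responsibility collapsed; reinitializing "
                "from a seeded quantile",
                RuntimeWarning,
                stacklevel=2,
            )
            logger.warning("EM component collapse at iteration %d", it)
            idx = np.where(collapsed)[0]
            for k in idx:
                q = float(rng.uniform(0.05, 0.95))
                lvl = _quantile_level(hist, q)
                if sigma_r is not None and k == 0:
                    sigma_r = max(lvl / np.sqrt(np.pi / 2), 1.0)
                else:
                    j = k - (1 if sigma_r is not None else 0)
                    means[j] = lvl
                    sds[j] = max(np.sqrt(hist.var()) / len(means), SD_FLOOR)
            # give each revived component a small weight; keep the others'
            # relative weights intact
            w[idx] = 0.05
            w = w / w.sum()
            continue

        prev = _stack_params(w, sigma_r, means, sds)
        w = mass / n
        k0 = 0
        if sigma_r is not None:
            r0 = resp[0] * h
            sigma_r = float(np.sqrt(np.sum(r0 * t**2) / (2 * np.sum(r0))))
            sigma_r = max(sigma_r, 1e-6)
            k0 = 1
        for j in range(len(means)):
            rj = resp[k0 + j] * h
            s = rj.sum()
            means[j] = float(np.sum(rj * t) / s)
            var = float(np.sum(rj * (t - means[j]) ** 2) / s)
            sds[j] = max(np.sqrt(var), SD_FLOOR)

        cur = _stack_params(w, sigma_r, means, sds)
        rmse = float(np.sqrt(np.mean((cur - prev) ** 2)))
        if rmse < tol:
            converged = True
            break

    # final log-likelihood after the last update
    dens = _densities(t, sigma_r, means, sds)
    total = (w[:, None] * dens).sum(axis=0)
    trace.append(float(np.sum(h * np.log(np.maximum(total, 1e-300)))))

    params = _assemble(spec, w, sigma_r, means, sds)
    return EMResult(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
    )


def _densities(t, sigma_r, means, sds) -> np.ndarray:
    rows = []
    if sigma_r is not None:
        rows.append(_rayleigh_pdf(t, sigma_r))
    for mu, sd in zip(means, sds):
        rows.append(_gauss_pdf(t, mu, sd))
    return np.vstack(rows)


def _assemble(spec, w, sigma_r, means, sds) -> MixtureParams:
    """Order Gaussians by mean (target = brightest when present) and tag."""
    order = np.argsort(means, kind="stable")
    means = np.asarray(means)[order]
    sds = np.asarray(sds)[order]
    k0 = 1 if sigma_r is not None else 0
    w = np.concatenate([w[:k0], np.asarray(w[k0:])[order]])
    w = np.clip(w, 1e-12, None)
    w = w / w.sum()
    classes = [BACKGROUND] * spec.n_components
    if spec.n_target_gaussians:
        classes[-1] = TARGET
    return MixtureParams(
        weights=w,
        rayleigh_sigma=sigma_r,
        gauss_means=means,
        gauss_sds=sds,
        classes=tuple(classes),
    )


def likelihood_energy(img: GrayImage, params: MixtureParams) -> EnergyMapPair:
    """Per-pixel negative log class-conditional likelihoods.

    The background density renormalizes the background components among
    themselves; the target density is the target Gaussian alone.  Class
    priors are *not* included here — they belong to the MRF prior, and
    folding them in as well would double-count them.  Probabilities are
    floored at ``P_FLOOR`` so energies stay within ``[0, E_MAX]``.
    """
    levels = np.arange(img.max_level + 1, dtype=np.float64)
    dens = params.component_densities(levels)
    cls = np.asarray(params.classes)
    bg = cls == BACKGROUND
    fg = cls == TARGET
    if not fg.any():
        raise ValueError("params have no target component")
    w_bg = params.weights[bg]
    p_bg = (w_bg / w_bg.sum()) @ dens[bg]
    p_fg = dens[fg][0]
    e_bg_lut = -np.log(np.maximum(p_bg, P_FLOOR))
    e_fg_lut = -np.log(np.maximum(p_fg, P_FLOOR))
    return EnergyMapPair(e_bg=e_bg_lut[img.pixels], e_fg=e_fg_lut[img.pixels])
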