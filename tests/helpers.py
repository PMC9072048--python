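"""Shared test utilities: independent oracles and synthetic inputs."""

from __future__ import annotations

import numpy as np

from curviseg.iohub import Histogram


def sample_mixture_hist(
    weights, rayleigh_sigma, means, sds, n, seed, max_level=255
) -> tuple[Histogram, np.ndarray]:
    """Draw n gray levels from a Rayleigh+Gaussian mixture (component 0 is
    the Rayleigh when rayleigh_sigma is not None), clip/round to integer
    levels, and return the histogram plus the raw sample."""
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    comp = rng.choice(len(weights), size=n, p=weights)
    x = np.empty(n)
    j0 = 0
    if rayleigh_sigma is not None:
        x[comp == 0] = rng.rayleigh(rayleigh_sigma, int((comp == 0).sum()))
        j0 = 1
    for j, (mu, sd) in enumerate(zip(means, sds)):
        m = comp == j0 + j
        x[m] = rng.normal(mu, sd, int(m.sum()))
    lv = np.clip(np.round(x), 0, max_level).astype(np.int64)
    return Histogram(np.bincount(lv, minlength=max_level + 1), n), lv


def per_pixel_em_step(pixels, w, sigma_r, means, sds):
    """One naive per-pixel EM iteration (E-step + closed-form M-step),
    written directly from the mixture definitions: responsibilities for
    every pixel, sums over pixels.  Independent of the histogram-weighted
    implementation."""
    x = np.asarray(pixels, dtype=float).ravel()
    n = len(x)
    comps = []
    if sigma_r is not None:
        dens_r = np.where(x >= 0, (x / sigma_r**2) * np.exp(-(x**2) / (2 * sigma_r**2)), 0)
        comps.append(dens_r)
    for mu, sd in zip(means, sds):
        comps.append(np.exp(-((x - mu) ** 2) / (2 * sd**2)) / (sd * np.sqrt(2 * np.pi)))
    dens = np.vstack(comps)
    weighted = np.asarray(w)[:, None] * dens
    resp = weighted / np.maximum(weighted.sum(axis=0), 1e-300)

    w_new = resp.sum(axis=1) / n
    k0 = 0
    sigma_new = sigma_r
    if sigma_r is not None:
        r0 = resp[0]
        sigma_new = float(np.sqrt(np.sum(r0 * x**2) / (2 * r0.sum())))
        k0 = 1
    means_new, sds_new = [], []
    for j in range(len(means)):
        rj = resp[k0 + j]
        mu = float(np.sum(rj * x) / rj.sum())
        var = float(np.sum(rj * (x - mu) ** 2) / rj.sum())
        means_new.append(mu)
        sds_new.append(max(np.sqrt(var), 0.5))
    return w_new, sigma_new, np.array(means_new), np.array(sds_new)


def brute_force_two_level_threshold(hist: Histogram) -> int:
    """Optimal k=2 quantizer of a gray histogram: the cut minimizing
    within-cluster squared error, found by exhaustive search over all cut
    points.  Returns the first level assigned to the upper cluster."""
    t = hist.levels
    h = hist.counts.astype(float)
    best_cut, best_cost = None, np.inf
    for cut in range(1, len(t)):
        lo_h, hi_h = h[:cut], h[cut:]
        if lo_h.sum() == 0 or hi_h.sum() == 0:
            continue
        m_lo = np.sum(t[:cut] * lo_h) / lo_h.sum()
        m_hi = np.sum(t[cut:] * hi_h) / hi_h.sum()
        cost = np.sum(lo_h * (t[:cut] - m_lo) ** 2) + np.sum(hi_h * (t[cut:] - m_hi) ** 2)
        if cost < best_cost:
            best_cost, best_cut = cost, cut
    return best_cut
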