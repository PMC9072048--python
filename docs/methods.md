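# Methods

This note documents the models implemented in curviseg, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical decisions that affect results.

## Image model

Images are 2-D single-channel rasters, 8- or 16-bit, coordinates
(row, col) with row 0 at the top.  Gray levels stay integer for histogram
work; feature and energy computations use intensities normalized to [0, 1]
by division by the maximum level, which also makes the noise-variance
convention bit-depth independent (a variance of 0.06 means the same
physical contrast perturbation at 8 and 16 bit).

## Gray-level mixture and EM

The gray histogram is modeled as one Rayleigh component (dark, low-gray
background mass), K background Gaussians (mid-gray tissue; default K = 2),
and one target Gaussian (the bright curvilinear class).  EM runs on the
histogram: responsibilities are computed once per gray level and weighted
by the level count.  This is algebraically identical to per-pixel EM
(verified in the tests against a per-pixel oracle) at O(L) instead of
O(N) per iteration, L the number of gray levels.

M-steps are the closed forms obtained by zeroing the derivative of the
expected complete-data log-likelihood:

- weights `w_k = Σ_t h_t r_kt / n`
- Gaussian `μ_k = Σ_t h_t r_kt t / Σ_t h_t r_kt`, variance analogously
- Rayleigh `σ² = Σ_t h_t r_t t² / (2 Σ_t h_t r_t)`

**Initialization** is deterministic from histogram quantiles: the Rayleigh
scale from the mean of the lowest-quartile mass (via E[t] = σ√(π/2));
background Gaussians at evenly spaced quantiles of the mass above that
quartile; the target Gaussian at the 0.995 quantile.  The top-quantile
start matters: the bright class typically holds only a few percent of the
pixels, so an evenly spaced slot would start the target inside a
background mode and EM then converges to a local optimum that merges the
two (observed directly on zero-noise phantoms before this choice).

**Convergence**: RMSE of the stacked parameter vector between iterations
below 1e-6, cap 500 iterations.  **Guards**: component sds floored at 0.5
gray levels and probabilities floored at 1e-12 (energy cap
−ln 1e-12 ≈ 27.63) to prevent singular likelihood spikes; a component
whose responsibility mass collapses below 1e-8·n is re-seeded at a random
quantile with weight 0.05 and a warning.  Re-seeding can transiently break
log-likelihood monotonicity; the ascent property holds for uninterrupted
runs and is tested on such runs.

On noisy phantoms the clipping of Gaussian noise at gray level 0 creates
a spike the mixture does not describe; in practice one background Gaussian
pins itself to level 0 at the sd floor and absorbs it.  This is benign for
segmentation (the component is tagged background) but can leave the
parameter RMSE jittering above tolerance, so noisy fits may report
`converged: False` at the iteration cap while the labeling is stable.

**Class-conditional energies**: p(x|background) renormalizes the
background components among themselves; p(x|target) is the target Gaussian
alone.  Class priors are deliberately *not* folded in here — the MRF prior
plays that role, and including mixture weights as well would double-count
prior information.

## Multiscale Hessian line similarity

Second derivatives at scale s are computed with separable sampled
Gaussian-derivative kernels truncated at 4s, reflective boundaries,
multiplied by s^γ with γ = 2 (the standard normalization for second-order
ridge detection, making responses comparable across scales).  The sampled
kernels are moment-corrected — Σw = 0 and Σk²w = 2 for the second
derivative, Σw = 0 and Σkw = 1 for the first — so the filters are exact on
polynomials up to order 2; without the correction, plain sampled-Gaussian
filtering is off by O(1) on quadratic images at small scales.

Eigenvalues of the 2×2 Hessian are closed-form; ordering is by absolute
value, ties by signed value ascending.  The line-similarity measure is the
two-dimensional Frangi vesselness

v = exp(−(λ₁/λ₂)² / 2β_r²) · (1 − exp(−(λ₁² + λ₂²) / 2c²)),  v = 0 if λ₂ ≥ 0,

bright-on-dark by default (the sign test flips for dark structures).
Defaults: β_r = 0.5; c adapts per scale to half the maximum Frobenius norm
of the Hessian over the image (so a flat image responds 0 and contrast is
auto-scaled); scale grid {1, 2, 3, 4, 6, 8} px chosen to bracket stroke
widths 1–10 px with the argmax within one grid step of a dense-grid
argmax (tested).  The per-pixel maximum over scales and its argmax scale
form the feature map; the argmax scale estimates local structure width.

## MRF energy and ICM

E(y) = Σᵢ e_{yᵢ}(i) + β·#{4-neighbor label disagreements} + α·Σᵢ m(yᵢ, vᵢ),

with m(feature, v) = 1 − v and m(background, v) = v.  The pairwise term is
the isotropic MLL (Potts) model on 4-neighborhoods, each unordered pair
counted once.  Defaults β = 1.5, α = 1.0: β in the 1–2 range trades
speckle suppression against thin-structure erosion at these energy scales
(likelihood energies are a few nats per pixel); α = 1 makes a unit of
line-feature evidence comparable to a nat of gray-likelihood evidence.

ICM initializes at the per-pixel ML labeling (ties to background) and
sweeps in deterministic raster order; each update minimizes the local
conditional energy, ties keeping the current label.  Every accepted move
lowers the total energy, so the per-sweep trace is non-increasing and
termination (no-change sweep, cap 100) is guaranteed; the output is
1-flip locally optimal.  Known limitation of coordinate descent: for very
large β the *global* minimizer is uniform, but ICM can stabilize at
blockwise splits that are 1-flip optimal; only scattered minority pixels
are guaranteed to be absorbed.  The inner sweep is numba-compiled (pure
sequential raster updates do not vectorize).

## Boundary refinement

The refinement is a deterministic geometric operator on label fields:
boundary map b (1 where any 4-neighbor disagrees), direction map d
(eight compass codes, E=0 counterclockwise to SE=7) pointing from each
boundary pixel to its nearest same-label interior pixel (Euclidean
distance; equidistant candidates resolved by the fixed priority
E>NE>N>NW>W>SW>S>SE; a label with no interior pixels anywhere leaves the
sentinel and the pixel unrefined), and label remapping: each boundary
pixel takes the input label at p + round(r·û), û the unit compass offset
(diagonals (±1, ±1)), rounding half-away-from-zero, out-of-range targets
ignored.  All reads are from the input field (simultaneous update);
interior pixels are bit-preserved; r = 0 is the identity; refinement is
applied per pixel regardless of class.  Default r = 1.0 — the factor is a
manual control by design.  The net effect at r = 1 is to re-decide
boundary pixels from one step toward the more reliable interior, which
removes detached misclassified fringe pixels while leaving clean straight
edges fixed (idempotence on half-planes is tested).

## Synthetic phantoms

A phantom is a tree of smooth strokes: seeded unit-step random walks with
per-step angular jitter (default 0.15 rad) and binary branching to a
configurable depth, each branch dilated to an integer width sampled from
[2, 6] px.  Foreground pixels draw gray levels from the target Gaussian
(mean 200, sd 12), background pixels from the three-component mixture
(Rayleigh σ = 20 with weight 0.40, Gaussians (80, 12) and (120, 15) with
weights 0.35 and 0.25) — modes separated by more than 3 sds so the
mixture is identifiable.  Zero-mean Gaussian noise of configurable
variance is added on the normalized scale, then clipped to [0, 1] and
re-quantized (round half up).  Default field 512×512, 8-bit, 4 root
branches, depth 2, giving foreground fractions of roughly 3–10 %.

What the phantoms do *not* emulate: spatially correlated background
texture, illumination gradients, partial-volume blur at stroke edges,
anatomical curvature statistics, and imaging-system noise that is neither
additive nor Gaussian.  Passing tests on phantoms therefore demonstrate
the internal correctness and noise behavior of the pipeline under its own
statistical assumptions, not clinical performance.

## Evaluation

Confusion metrics treat foreground as positive; accuracy, sensitivity,
specificity, per-class IoU and their two-class mean (MIoU) are reported;
the correct-calls-over-all-calls ratio is reported alongside accuracy (it
is the same number by construction, kept under both names for
traceability).  Ratios with empty denominators are reported as None,
never NaN.  Segmentation error is 1 − accuracy.  The baseline is
two-cluster Lloyd's on the gray histogram, centroids initialized at the
right-sided 25th/75th percentile levels (the first level strictly above
the quantile mass — this initialization reaches the optimal two-level
quantizer on tie-heavy histograms where the left-sided variant stalls in
a worse fixed point), the brighter cluster labeled feature.  The
noise-robustness harness sweeps noise variances over seeded phantom
ensembles and reports mean ± sd error with full per-seed provenance.

## Problem sizes

Default experiment sizes were chosen to exercise the study conditions at
desk scale: 20 phantoms of 512×512 for the pipeline-vs-baseline
comparison, 10 seeds per variance for robustness sweeps, 50 phantoms of
64×64 for ICM trace checks, and n = 1e5 samples per histogram (20 seeds)
for EM recovery.  All are configurable.
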