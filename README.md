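# curviseg

Segmentation of bright curvilinear structures — vessel-like, tree-branching
features of varying width — in 2-D grayscale medical images, using a hybrid
statistical/geometric pipeline rather than a trained network:

1. **Gray-level mixture model.** The histogram of gray levels is modeled as
   a finite mixture: one Rayleigh component and two Gaussians for the
   background, plus one Gaussian for the bright target class,

   p(t) = w₀ f_Ray(t; σ) + w₁ N(t; μ₁, σ₁²) + w₂ N(t; μ₂, σ₂²) + w₃ N(t; μ₃, σ₃²),

   with f_Ray(t; σ) = (t/σ²) exp(−t²/2σ²).  Parameters are estimated by
   EM run on the histogram (responsibilities per gray level, weighted by
   the level frequency), which is exactly equivalent to per-pixel EM but
   O(gray levels) per iteration.

2. **Multiscale Hessian line features.** Scale-normalized second
   derivatives L_xx, L_xy, L_yy (Gaussian-derivative filters, γ = 2) give
   Hessian eigenvalues |λ₁| ≤ |λ₂| per pixel; a Frangi-style line
   similarity v = exp(−(λ₁/λ₂)²/2β_r²)·(1 − exp(−(λ₁²+λ₂²)/2c²)), zeroed
   where λ₂ ≥ 0, is maximized over a scale grid so structures of any width
   respond at their matching scale.

3. **MRF labeling by ICM.** Binary labels y minimize
   E(y) = Σᵢ −ln p(xᵢ|yᵢ) + β·#{4-neighbor disagreements} + α·Σᵢ mismatch(yᵢ, vᵢ),
   an isotropic MLL/Potts prior fused with the line-feature term, via
   raster-order iterated conditional modes from the maximum-likelihood
   initialization.

4. **Boundary refinement.** Boundary pixels (any 4-neighbor disagreement)
   get one of eight compass directions toward the nearest interior pixel
   of their own label; each boundary label is remapped from the offset
   coordinate scaled by a manual factor r.  Interior pixels never change.

Because clinical data for this problem is typically not redistributable,
the package ships a seeded phantom generator (`curviseg.synth`) producing
tree-structured bright strokes over a Rayleigh+Gaussian background with
controllable Gaussian noise, plus an evaluation harness
(`curviseg.evalmod`) with confusion-matrix metrics, a gray-level K-means
baseline, and a noise-robustness experiment.

## Worked example

```python
from curviseg import CurvilinearModel, PhantomConfig, RunConfig, generate_phantom

pair = generate_phantom(PhantomConfig(height=256, width=256, seed=11))
res = CurvilinearModel(pair.image, config=RunConfig(seed=11)).fit()
print(res.summary())
rep = res.evaluate(pair.truth)
print(f"accuracy={rep.accuracy:.4f}  sensitivity={rep.sensitivity:.4f}  "
      f"specificity={rep.specificity:.4f}  MIoU={rep.miou:.4f}")
```

prints

```
Curvilinear segmentation results
========================================================
image: 256 x 256, 8-bit
foreground fraction: 0.0805

Gray mixture (histogram EM)
--------------------------------------------------------
component                weight    location    spread
rayleigh (background)    0.3689       19.90
gaussian (background)    0.3321       80.31     12.64
gaussian (background)    0.2179      121.00     14.59
gaussian (target)        0.0811      199.86     11.91

EM iterations: 215 (converged: True); final log-likelihood: -334858.68
ICM sweeps: 2; energy 327019.48 -> 327019.48
config: beta=1.5, alpha=1.0, r=1.0, scales=[1.0, 2.0, 3.0, 4.0, 6.0, 8.0]

accuracy=0.9986  sensitivity=0.9880  specificity=0.9996  MIoU=0.9907
```

The phantom was generated with background modes at gray levels ~20
(Rayleigh scale), 80 and 120, and a bright target at 200; the fitted
mixture recovers all four, and the final labeling agrees with the ground
truth on 99.9 % of pixels.  The same pipeline is available from the shell:

```sh
curviseg simulate --seed 11 --out-dir phantom/
curviseg segment --in phantom/image.png --out mask.png --summary
curviseg evaluate --pred mask.png --truth phantom/truth.png
curviseg robustness --variances 0.0,0.02,0.06,0.10 --n-seeds 5 --out-csv rob.csv
```

## Layout

- `curviseg.iohub` — raster types, PNG/TIFF I/O, histogram, YAML config
- `curviseg.mixture` — Rayleigh+Gaussian mixture, histogram EM, likelihood energies
- `curviseg.linefeat` — Hessian filters, eigenvalues, multiscale line similarity
- `curviseg.mrf` — MLL/Potts + feature energies, ICM
- `curviseg.refine` — boundary/direction/offset refinement
- `curviseg.synth` — phantom generator
- `curviseg.evalmod` — metrics, K-means baseline, robustness harness
- `curviseg.model` — `CurvilinearModel` / `CurvilinearResults` front end
- `curviseg.cli` — `curviseg` command-line tool

See `docs/methods.md` for the modeling assumptions, parameter defaults,
and known limitations.
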