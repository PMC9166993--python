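# lungtomo

A parallel-beam CT simulation and reconstruction toolkit for studying
**iterative (algebraic) reconstruction of low-dose, limited-angle lung
imaging**. It is aimed at researchers and students who want a small,
fully-inspectable sandbox in which the classic comparison between algebraic
reconstruction (ART/Kaczmarz) and filtered back projection (FBP) can be run
end to end: phantom → projection → photon noise → reconstruction → image
quality metrics.

The motivating imaging context is paediatric bronchiolitis obliterans (BO)
on high-resolution CT: mosaic perfusion (patchy low-attenuation lung),
thickened airway walls, and attenuated vessels — structures that are easily
degraded by the noise and artifacts of low-dose, limited-angle acquisition.
The bundled lung phantom emulates these signs on a synthetic thorax slice.

## The model

The image is a square attenuation map flattened into a vector
*x ∈ ℝⁿ*. Each measurement ray *i* contributes one linear equation, with
weights *r,ᵢⱼ* given by the intersection of the ray (a strip of detector
width, or a zero-width line) with pixel *j*:

    p = R x + e,        R ∈ ℝ^{m×n}  (sparse system matrix)

**ART (Kaczmarz)** projects the iterate onto one measurement hyperplane at
a time with relaxation λ ∈ (0, 2):

    x ← x + λ (pᵢ − ⟨aᵢ, x⟩) / ‖aᵢ‖²  aᵢ

On a consistent system it converges to a solution (from a zero start, the
minimum-norm solution); on an inconsistent one the iterates cycle, and the
toolkit can return the average over the final sweep instead. **SIRT**
applies all ray corrections simultaneously per sweep with row/column
normalisation. **Regularized least squares** minimises
`‖p − Rx‖² + w·xᵀ(B + I)x` with B the 4-neighbour Laplacian (local
uniformity) solved by a sparse augmented LSMR. **FBP** is the standard
ramp-filtered back projection baseline.

Low-dose acquisition follows the Beer–Lambert counting model: per detector
bin, `N ~ Poisson(I₀·e^{−p})`, and the measured line integral is
`p′ = −ln(N/I₀)`. Image quality is scored with MSE, RMSE, ISNR, PSNR and
SSIM, plus line-profile total variation for stability comparisons.

## Worked example

The default protocol: 64×64 lung phantom, 90 views spanning [0°, 90°) at 1°
steps (true limited angle), strip-beam projection, 10⁴ incident photons per
bin, ART (λ = 0.25, 10 sweeps) vs FBP (ramp filter):

```python
import lungtomo as lt

result = lt.run_comparison(lt.bo_protocol())
print(result.table.pivot(index="metric", columns="algorithm", values="value").round(4))
```

```
algorithm       ART      FBP
metric
emse         0.1170   0.1932
isnr         4.3539      NaN
mse          0.0137   0.0373
profile_tv   4.8330   5.5707
psnr        18.6353  14.2813
ssim         0.4758   0.3446
```

ART reconstructs the noisy limited-angle data with roughly one third of
FBP's mean squared error, 4.4 dB higher PSNR (the `isnr` row is ART's
improvement over the FBP baseline), higher structural similarity, and a
smoother central row profile (lower total variation) — the classic
"smoother, clearer, closer to the original" advantage of iterative
reconstruction in this regime.

The convergence study exposes *semi-convergence*: with noisy limited-angle
data the per-sweep MSE against the original first falls, reaches a minimum
(sweep 36 under the default protocol), then grows as the iterates begin
fitting noise, while the noiseless control curve is non-increasing:

```python
study = lt.run_convergence_study(lt.bo_protocol())
print(study.best_sweep("noisy"))   # -> 36
```

A `lungtomo` command-line interface wraps the same pipeline
(`lungtomo phantom | project | noise | recon | metrics | compare | converge`);
see `lungtomo --help`.

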