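# Methods

This note documents the models, conventions, numerical choices and
limitations of the toolkit, in the order of the pipeline.

## Geometry and the system matrix

* Coordinates: image centred at the origin, x right, y up; pixel centres at
  half-integer offsets; pixels flattened row-major from the top-left. The
  view angle θ is measured counterclockwise from the +x axis and defines
  the detector coordinate `s = x·cosθ + y·sinθ`; a ray is a level set of
  `s`. Rays are indexed angle-major. These conventions are recorded in
  `SystemMatrix.meta` so matrix, image vector and sinogram always agree.
* Two beam models. `strip` (default): a ray is a band of width equal to
  the detector spacing and the weight of pixel j is the intersection area
  divided by the pixel area δ² — dimensionless, in [0, 1]. `line`: the
  weight is the chord length of the zero-width ray through the pixel.
  Both use the exact piecewise-quadratic overlap of a square with a
  half-plane (the trapezoidal "projection profile" of a square), so
  weights match brute-force polygon clipping at machine precision; the
  test suite checks this entrywise on all grids up to 8×8 against a
  shapely clipping oracle.
* Degenerate boundary case: in line mode on axis-aligned views, a ray that
  falls exactly on a shared pixel edge is assigned to exactly one of the
  two pixels (half-open interval), so tiled columns are neither dropped
  nor double-counted.
* Units. A strip sinogram is in attenuation units (area ratios ×
  pixel values); a line sinogram is attenuation × length. Consumers that
  need physical optical depth (the noise model, FBP) convert with the
  factor δ²/w (w = detector spacing); with the default w = δ this is
  simply δ.

## Phantoms

* Rasterisation is by pixel-centre inclusion, no anti-aliasing: counting
  oracles (e.g. pixels inside a disk) are then exact, and rendering is
  idempotent. Primitives are painted in list order (`replace`) or summed
  (`additive`).
* The lung phantom places, inside a soft-tissue thorax ellipse (relative
  attenuation 0.50), two lung fields (0.10) containing 3–5 mosaic-
  perfusion patches per lung (0.04 — darker than the surrounding lung),
  2–4 vessel lines per lung (0.35, width ≥ 1 px) fanning from the hilum,
  and 1–2 airway cross-sections per lung drawn as an air lumen (0.03)
  ringed by a thickened wall (0.35, thickness ≥ 1 px). All placement draws
  come from a single NumPy `default_rng` (PCG64) stream, so a given
  (grid_size, seed) is bit-reproducible; a placement manifest (class,
  centre, sizes, value) accompanies the image.
* Values live on a relative [0, 1] scale (air = 0). The default pixel size
  is 4.0/grid_size, chosen so a ray through the mediastinum accumulates
  optical depth ≈ 2 (transmission ≈ e⁻²), a physically sensible regime
  for the counting noise model. This scale was fixed once when the
  protocol was designed.
* What the phantom does **not** model: anatomical airway trees, lung
  texture, respiratory/cardiac motion, 3D partial-volume effects, scanner
  blur, beam hardening or scatter. Passing tests therefore demonstrate
  algorithmic behaviour (convergence, noise response, artifact structure),
  not clinical image quality on real HRCT.

## Noise model

Per detector bin with clean optical depth p: `N ~ Poisson(I₀·e^{−p})`,
clamped at ≥ 1 count (photon starvation guard), measured
`p′ = −ln(N/I₀)`. Defaults: I₀ = 10⁵; the low-dose replication protocol
uses I₀ = 10⁴. A variance-matched additive-Gaussian domain
(σ² = 1/(I₀·e^{−p})) is provided for cross-checks; a Monte-Carlo test
verifies the Poisson path against this delta-method prediction. One seeded
PCG64 stream per call; the transform round-trips exactly when the drawn
count equals its mean.

## Reconstruction

* **ART / Kaczmarz** `x ← x + λ(pᵢ − ⟨aᵢ,x⟩)/‖aᵢ‖² aᵢ`, one pass over all
  rays per sweep, cyclic (default) or seeded-shuffled order. λ is constant
  per run. Stopping: relative residual ‖p − Rx‖/‖p‖ ≤ `stop_tol`, or
  residual stagnation (relative change ≤ `stop_tol`), or `max_sweeps`;
  `stop_tol = 0` disables early stopping.
* Row guard: rays whose squared norm falls below `row_norm_cutoff` (default
  10⁻⁴) times the largest row norm are skipped, generalising the
  zero-norm-row rule. Rationale: a strip ray that barely clips a grid
  corner carries almost no signal, but the Kaczmarz update divides the
  (noisy) residual by ‖aᵢ‖ and would inject unbounded noise into a handful
  of pixels. On the protocol geometry the row-norm distribution is sharply
  bimodal (interior rays ≥ ~20, grazers ≤ ~10⁻³), so the cutoff is
  insensitive over several orders of magnitude.
* Incompatible systems: `cycle_average` runs one extra sweep after the
  main loop and returns the mean of the per-ray iterates — the natural
  point estimate when the iterates only cycle. The default is
  `last_iterate`.
* **SIRT**: `x ← x + λ·C·Aᵀ·R·(p − Ax)` with R, C the inverse row-/column-
  sum diagonals of |A|.
* **Regularized least squares**: minimises `‖p − Rx‖² + w·xᵀ(B + I)x`,
  B = 4-neighbour graph Laplacian (so xᵀBx is the sum of squared
  adjacent-pixel differences; set `smoothness="none"` for pure ridge).
  Solved deterministically via LSMR on the stacked system
  `[R; √w·D; √w·I]` with DᵀD = B. Default weight `w = 0.01·‖R‖²_F/n`
  when unset. At w = 0 a singular normal system is detected exactly
  (dense rank check) on systems up to ~4·10⁶ entries and reported with
  the suggestion to regularize.
* **FBP**: frequency-domain filtering with the discrete band-limited ramp
  (Kak–Slaney kernel; `shepp-logan` and `hann` windows available),
  zero-padded to a power of two, followed by back projection with linear
  interpolation along the detector. Each view carries angular weight
  π/n_views — the convention of standard implementations — which keeps
  amplitude approximately correct under limited-angle and sparse-view
  sampling alike (with actual-spacing weights a [0°, 90°) acquisition
  reconstructs at half amplitude). A single-view sinogram is accepted but
  flagged. Cross-checked against an independent FBP implementation
  (scikit-image `iradon`) on matched geometry.

## Metrics

MSE, RMSE (√MSE), ISNR = 10·log₁₀(MSEᵢₙ/MSEₒᵤₜ) dB relative to a baseline
reconstruction, PSNR = 10·log₁₀(peak²/MSE) dB. The PSNR peak defaults to
the declared dynamic range of the reference (candidate-independent and
deterministic); the literal "maximum of the reconstruction" reading is
available by passing `peak` explicitly. SSIM uses a 7×7 uniform window,
k₁ = 0.01, k₂ = 0.03, data range from the declared image range, with the
per-window sample covariance as the cross term; computation is delegated
to scikit-image's `structural_similarity` and pinned by a hand-evaluated
closed-form case in the tests. Degenerate perfect-reconstruction inputs
raise a dedicated signal rather than returning infinities silently
(batch comparison maps them to `inf`).

## Replication protocol

The "90° projection angle" acquisition is interpreted primarily as
**90 views spanning [0°, 90°) at 1° steps** — a true missing-wedge
limited-angle problem; the alternative reading (90 views spread over
[0°, 180°)) is available via `bo_protocol(angles_over_180=True)`.
Protocol defaults, fixed once at design time: 64×64 lung phantom
(phantom seed 7), 95 detector bins at spacing δ, strip beam, I₀ = 10⁴
(noise seed 11), ART with λ = 0.25 and 10 sweeps for the comparison, FBP
with the ramp filter. λ = 0.25 is the standard under-relaxation choice
for noisy data: at λ = 1 the ART iterate carries noise speckle that
inflates its profile total variation above FBP's, while under-relaxation
smooths the iteration without sacrificing fidelity. The convergence study
runs 150 sweeps with stopping disabled so the semi-convergence minimum
(sweep ≈ 36–48 under these conditions) sits well inside the budget.

Problem sizes throughout (64×64 and 128×128 grids, ≤ 180 views) are
desk-scale choices that keep any single study in the tens of seconds.

## Known limitations

* The comparative ART-vs-FBP orderings are statements about this protocol
  (phantom family, dose, angle set, λ, sweep count), not universal
  rankings; at full-angle high dose FBP is competitive or better.
* The energy-conservation check for FBP holds on full-angle noiseless
  data (reconstruction sum over the support within 5% of the original);
  under limited angle both methods lose or displace energy, and ART's
  peak-amplitude deficit is reported, not asserted, because its magnitude
  is protocol-dependent.
* Maximum-entropy reconstruction is not implemented; SIRT is included as
  a documented extension of the row-action family.
* The explicit sparse system matrix targets grids ≤ 256²; larger problems
  would need a matrix-free projector.
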