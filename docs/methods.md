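# Methods

## Model

Multi-coil complex diffusion-MRI data are redundant: a small spatial block of
`k × k × k` voxels, stacked over `C` receiver channels and `V` diffusion
volumes, forms an `M × N` matrix (`M ≤ N`, aspect ratio `δ = M/N`) whose
signal part is low-rank while thermal noise — Gaussian in the complex domain —
fills the singular spectrum with a Marchenko–Pastur (MP) bulk.  In noise
units `y = s/(σ√N)` the pure-noise bulk occupies `[1−√δ, 1+√δ]`, so any
component with `y` above the bulk edge is attributable to signal and anything
below is noise.

All recovery strategies operate on this normalized spectrum and reconstruct
`Ŝ = U diag(σ√N·η(y)) Vᵀ`:

| strategy | η(y) | behavior |
|---|---|---|
| `tsvd` | y above the bulk edge, else 0 | keep-or-kill at the edge |
| `hard` | y above `y†(δ)`, else 0 | keep-or-kill at the asymptotically optimal level |
| `soft` | `y − (1+√δ)` above the edge | uniform shrinkage |
| `fro` | `√((y²−δ−1)²−4δ)/y` | optimal for Frobenius loss |
| `op` | `z(y)` | optimal for operator loss |
| `nuc` | `(z⁴−δ−√δ·yz)/(z²y)` where positive | optimal for nuclear loss (most aggressive) |
| `mp_pca` | keep the `P` supra-bulk values unchanged | MP fit, no debiasing |

with the debiased level `z(y) = √((y²−δ−1+√((y²−δ−1)²−4δ))/2)` for
`y ≥ 1+√δ`.  The discriminant is clamped at zero before the square root
(analytically non-negative above the edge; rounding can push it to −ε).  The
truncation threshold of `tsvd` is taken at the bulk edge `1+√δ` with ties
retained, consistent with the thresholds of the optimal shrinkers.

## Noise estimation

Two estimators serve the block pipeline:

* **Median estimator** (default for all shrinkers except MP-PCA):
  `σ̂ = s_med / √(N·μ½(δ))` where `μ½` is the MP median, found by bracketed
  root finding of the MP CDF (quadrature tolerance 1e−10).  At most `M/2`
  signal spikes can move the median, so the estimate ignores strong signal
  components.
* **MP fit** (used by MP-PCA): scan the signal count `P` upward and accept
  the first residual bulk whose spread fits inside the MP support width
  implied by its own mean (`(λ_{P+1}−λ_M)/(4√γ N) ≤ Σbulk/((M−P)N)`,
  `γ=(M−P)/N`).  When no bulk satisfies the exact MP-width condition — which
  happens when the noise level varies within the block, stretching the bulk —
  the most MP-consistent bulk (smallest spread/mean ratio) is used instead.
  A bulk of identical positive eigenvalues is not accepted (an MP law with
  σ>0 has positive width), so noise-free input is never consumed as noise;
  if the scan finds no valid bulk at all, everything is retained and σ̂=0.

A numerically-zero median (below 1e−6 of the top singular value; the
Gram-route eigendecomposition carries ~1e−8 relative noise in small singular
values) is treated as σ̂=0 and the block passes through unchanged.

## Pipeline

1. **Channel decorrelation** (optional): Mahalanobis whitening with the coil
   noise covariance Φ via its Hermitian inverse square root; Φ is read from
   plain-text matrices or estimated from background voxels (≥10 per channel;
   ridge `1e−6·tr(Φ)/C` when the condition number exceeds 1e8 — the
   conditioning policy is this package's choice).
2. **Phase unwinding** (two-pass): the real and imaginary parts are denoised
   independently with the same strategy and block plan as the main pass; the
   background phase is the argument of the denoised complex signal per
   voxel/channel/volume, and the data are rotated by its negative, leaving
   the signal real-dominant.  A *reliability gate* leaves voxels unrotated
   where the denoised magnitude is within twice the local noise level: there
   the estimated phase is dominated by residual noise correlated with the
   voxel's own noise, and rotating by it would rectify noise into the real
   part — exactly the floor the pipeline exists to remove.  The phase is
   estimated per volume independently (no temporal smoothing).
3. **Block-wise recovery**: blocks fully inside the volume (no padding, which
   would fabricate data and bias σ̂), default stride 1; every voxel is
   covered, interior voxels by `k³` blocks.  The block edge defaults to the
   smallest odd `k` with `k³ ≥ C·V` (`M = C·V ≤ N = k³`); a fixed kernel
   (e.g. 5) is available for method comparisons, with rows/columns oriented
   so `M ≤ N`.  σ̂ is estimated per block from its own spectrum, which
   absorbs slowly varying noise maps.
4. **Aggregation**: overlapping estimates are averaged with weights
   `1/(1+R)`, `R` the count of non-zero shrunk singular values, so cleaner
   (lower-rank) blocks dominate; σ̂ and rank maps aggregate with the same
   weights.
5. **Reconstruction**: optional phase rewinding (off by default — after
   unwinding only the real part carries signal), root-sum-of-squares or
   sensitivity-weighted channel combination.

With unwinding disabled the real and imaginary parts are denoised
independently; this is the right mode when no background phase is present
but complex coil sensitivities put signal in both parts.

A multi-strategy pass evaluates several shrinkers from one Gram
eigendecomposition per block, reconstructing each strategy from its retained
components only; it is numerically identical to independent runs
(`float32` accumulation for the multi-strategy sweep, `float64` for single
runs).

The magnitude-domain reference method applies MP-PCA to the channel-combined
magnitude in 5×5×5 blocks.  Because low-SNR magnitude data are Rician, the
noise floor there is a mean bias no zero-mean low-rank model can remove; the
reported σ map is corrected for Rician inflation by fixed-point iteration of
the analytical ξ(θ) moment factor (ξ(0)=2−π/2, ξ(∞)=1), while component
selection uses the raw MP fit.

## Synthetic phantom

The generator reproduces the statistical structure of a multi-coil diffusion
acquisition: `S̃_c = R_c·S·e^{iφ} + ε_r + iε_i`, `ε ~ N(0, σ(x)²)` i.i.d.
over voxels, channels, volumes and real/imaginary parts.

* **Compartments**: straight cylindrical fiber bundles (single-tensor
  attenuation, `D∥ = 1.7e−3 mm²/s`, `D⊥ = 0.4e−3 mm²/s`), crossings mixing
  bundle signals with equal volume fractions, and spherical free-water
  regions (`D = 3.0e−3 mm²/s`).  The mini phantom (16³ grid) holds one
  straight bundle, one crossing pair and one CSF-like sphere; the full
  configuration holds 27 bundles on a 48³ grid and 3 isotropic regions.
  Geometry is this package's own; compartment parameters, protocol, noise
  and phase models follow the acquisition being emulated.
* **Protocol**: 5 b=0 volumes plus 24/48/96 diffusion directions
  (golden-spiral hemisphere) at b = 1000/2000/3000 s/mm² — 173 volumes.
* **Coil model**: Gaussian lobes on a ring with alternating z offsets and
  per-channel linear phases.  The combined (root-sum-of-squares) amplitude
  is renormalized to a smooth radial envelope rising outward across the
  support; the envelope carries most of the SNR span so that the noise map
  itself varies gently.  On a full-scale grid a 5³ block sees an essentially
  constant σ; concentrating the entire SNR range into a 16³ grid's noise map
  would put a ~3× σ gradient inside single blocks — a scale artifact, not a
  property of the data being emulated.  Single-channel phantoms use R ≡ 1.
* **Noise map**: σ(x) = c·(1+g·exp(−(r/w)²)), highest at the center; the
  gentlest bump (widest w) that realizes the target is chosen and (g, c) are
  solved so the b=0 SNR spans exactly 2–15 over the support.
* **Background phase**: `A·sin(2πf_x x/X+ψ_{z,v})·sin(2πf_y y/Y+χ_{z,v})`
  with independent random shifts per slice and volume — smooth in-plane,
  abrupt across slices.  Default amplitude π/2 rad; the default frequency is
  1.5 cycles across a full-scale (~140 voxel) FOV *scaled to the grid in
  use*, so a denoising block sees the same intra-slice phase gradient as at
  full scale.
* **Reproducibility**: one root seed; independent streams for sensitivities,
  phase shifts and noise are spawned deterministically.

What the phantom does not emulate: k-space sampling artifacts (ghosting,
partial Fourier, multiband aliasing), motion, eddy currents, susceptibility
distortion, curved or dispersing fiber geometry, and coil noise correlation
(the simulator draws channel noise independently; whitening is exercised by
dedicated correlated-noise tests).  Passing tests therefore demonstrate the
statistical denoising behavior, not robustness to acquisition artifacts.

## Evaluation

* Mean-normalized error `mean |Ŝ−S|/S` over masked voxels and volumes;
  samples with vanishing truth (≤1e−6 of the maximum) are excluded with a
  reported count, since the ratio is unstable where the true signal is zero.
* PSNR `10·log10(1/MSE)` per b-shell after scaling both images by the
  truth's peak (making 1/MSE a true peak ratio).
* Noise floor: mean magnitude over a free-water region at the highest
  b-value, where the true signal (`e^{−9} S₀` at b=3000) is far below any
  realistic floor; `floor_ratio` reports the fold-reduction.
* Normalized residual maps `(before−after)/σ̂` with skewness/excess-kurtosis
  summaries (Gaussian-shaped residuals indicate noise removal without
  structure loss); voxel-wise SNR as mean magnitude over volumes divided by
  σ̂ (mean of voxel-wise ratios, +∞ sentinel where σ̂=0).
* Tractography connection score `1 − √((VC−1)²+IC²+NC²)/√2` on given
  valid/invalid/no-connection fractions (computing the fractions themselves
  is out of scope).

## Study problem sizes and design choices

* The noise-floor study runs the mini phantom at C=32, V=173 on the 16³
  grid with the fixed 5×5×5 kernel, stride 1, median noise estimator —
  small enough for a complete seven-strategy sweep on one CPU in minutes
  while keeping the block matrices (125 × 5536) deep in the regime the
  method targets.
* The planted-spike experiment uses a rank-1 truth with singular value
  `5σ√N` — clearly above the detection edge `(1+√δ)σ√N`, as the experiment
  requires a detectable signal component — and 100 seeded draws per matrix
  size.
* The channel-redundancy trend is measured the way multi-coil arrays are
  actually compared: coil subsets (1, 2, 4, 8 of a fixed 32-coil array,
  spread over the ring) of one paired noise realization, denoised with the
  fixed kernel and combined with the true sensitivities.  Collected signal
  grows with coil count while σ is fixed, and the error of the combined
  image decreases accordingly.  Subsets must be spread over the array:
  clustering them on one side leaves low-amplitude regions that dominate
  the error.
* Error evaluation for trend comparisons is restricted to the tissue
  support and to volumes retaining ≥5% of the voxel's b=0 signal, the
  in-contour analog of evaluating within tissue outlines; below that the
  normalized error measures only the floor.

## Numerical choices and limitations

* Blocks are processed via the `M×M` Gram matrix (eigendecomposition +
  projection), reconstructing from retained components only; this matches
  the direct SVD route to ~1e−8 relative and makes the exact round-trip
  guarantee (1e−10) apply to the direct `recover_matrix` path.
* Identity behavior: σ̂=0 blocks pass through bit-consistently; MP-PCA and
  the normalized-shrinkage path reproduce the input under identity
  shrinkage within 1e−10 (unit tested).
* Phase-estimation accuracy is SNR- and scale-dependent: components of the
  phase structure below the bulk edge are unrecoverable in principle.  At
  desk-scale block sizes this limits phase accuracy at low SNR; the
  reliability gate confines the resulting damage to zero-signal voxels.
  The 0.1-rad accuracy figure is verified in the regime where the phase
  structure is detectable (SNR ≥ 15 phantom).
* MP-PCA with a scalar per-block σ tolerates only mild within-block noise
  variation at small δ (the MP bulk width `4√δ·σ²` is narrow); the
  most-consistent-bulk fallback degrades gracefully rather than retaining
  everything.
* Stride > 1 trades speed for blocking artifacts and is warned about;
  block-boundary voxels are covered by fewer blocks (no padding).
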