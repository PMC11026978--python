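# mccdenoise

Noise-floor-suppressing denoising of multi-channel complex (MCC) diffusion
MRI via optimal singular-value shrinkage.

## The problem

The spatial resolution of diffusion MRI is capped by noise: at high
diffusion weighting the magnitude signal sinks below the Rician noise floor
and becomes unmeasurable, because taking the modulus of a low-SNR complex
signal rectifies noise into a positive bias.  Magnitude-domain denoisers
cannot remove that bias.  Per-coil *complex* data, however, have zero-mean
Gaussian noise and a great deal of redundancy across receiver channels and
diffusion volumes — redundancy a low-rank matrix model can exploit before
the bias is ever created.

`mccdenoise` implements this MCC denoising framework for researchers working
with raw multi-coil diffusion data or developing denoising methods:

* a local `k×k×k` spatial block stacked over `C` channels and `V` volumes
  forms an `M×N` signal-plus-noise matrix (`M ≤ N`, `δ = M/N`);
* in noise units `y = s/(σ√N)` the pure-noise singular values fill the
  Marchenko–Pastur bulk `[1−√δ, 1+√δ]`;
* each singular value is replaced by `σ√N·η(y)` with one of seven shrinkage
  rules: MP-PCA (`mp_pca`), truncation at the bulk edge (`tsvd`), optimal
  hard thresholding (`hard`), soft thresholding (`soft`), and the optimal
  shrinkers for Frobenius (`fro`), operator (`op`) and nuclear (`nuc`)
  norm loss, e.g.

  `η_fro(y) = √((y²−δ−1)² − 4δ)/y` for `y ≥ 1+√δ`, else 0;

* the noise level σ comes from the MP median of the block's own spectrum
  (`σ̂ = s_med/√(N·μ½(δ))`) or jointly with the signal count from an MP fit;
* the pipeline chains channel decorrelation (Mahalanobis whitening of the
  coil covariance), two-pass background-phase unwinding, block-wise
  recovery with rank-weighted aggregation (weights `1/(1+rank)`), and
  channel combination.

A synthetic multi-coil phantom (fiber bundles, crossings, a free-water
region, coil sensitivity maps, bidimensional-sinusoid background phase,
spatially varying noise with SNR 2–15) provides ground truth for every
stage, and an evaluation module scores error, PSNR, SNR maps, noise floors
and the tractography connection score.

## Worked example

```python
import numpy as np
from mccdenoise import (MCCDenoiser, combine_channels, default_phantom,
                        noise_floor, simulate_mcc)

cfg = default_phantom("mini", channels=32, seed=1, phase_amplitude=0.0)
image, truth = simulate_mcc(cfg)          # (16,16,16,32,173) complex + truth

den = MCCDenoiser(strategy="nuc", kernel=5, unwind=False)
denoised = den.transform(image.data)

floor_before = noise_floor(combine_channels(image.data, "sos"),
                           truth.csf_mask, truth.bvals)
floor_after = noise_floor(combine_channels(denoised, "sos"),
                          truth.csf_mask, truth.bvals)
print(f"CSF floor at b=3000: {floor_before:.3f} -> {floor_after:.3f} "
      f"({floor_before / floor_after:.1f}x lower)")
print(f"mean retained rank per block: {den.rank_map_.mean():.1f}")
```

prints

```
CSF floor at b=3000: 3.657 -> 0.154 (23.7x lower)
mean retained rank per block: 0.7
```

The free-water signal at b=3000 is truly ~1.2e-4 of the b=0 signal; the
noisy sum-of-squares magnitude floors at 3.66 (pure rectified noise), and
nuclear-norm shrinkage of the complex data lowers that floor 23.7-fold.
`MCCDenoiser` follows scikit-learn conventions (`get_params`/`set_params`,
fitted attributes `sigma_map_`, `rank_map_`, `report_`); plain functions
(`denoise_mcc`, `denoise_pass`, `denoise_matrix`) expose the same machinery.

## Command line

```sh
mccdenoise simulate --scale mini --channels 8 --seed 7 --out phantom/
mccdenoise run --real R.nii.gz --imag I.nii.gz --strategy nuc \
    --kernel auto --stride 1 --combine sos --out denoised/
mccdenoise baseline-mag --mag M.nii.gz --out baseline/
mccdenoise eval --denoised D.nii.gz --truth T.nii.gz --out report.json
mccdenoise toy-fig12 --sizes 20,50,100 --draws 100 --out toy.json
```

Complex images travel as real/imaginary (or magnitude/phase) NIfTI pairs
laid out `(x, y, z, channel, volume)`; protocols use FSL `.bval`/`.bvec`
text files; the coil covariance is a plain-text matrix.

## Documentation

`docs/methods.md` describes the model, the estimators, the phantom design
and its deliberate simplifications, numerical choices, and known
limitations.
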