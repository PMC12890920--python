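# Methods

## Restoration model

The network learns a mapping from a degraded image to its clean counterpart
from paired examples. Its core is the Beylkin–Coifman–Rokhlin (BCR)
nonstandard wavelet form: an integral operator expressed in a multilevel
basis becomes nearly sparse, acting band-by-band at each dyadic level. The
convolutional analogue used here replaces the fixed wavelet transforms with
learned stride-2 "restriction" convolutions, the band operators with small
stacks of local convolutions per level, and the inverse transform with
coarse-to-fine upsample-and-sum reconstruction. The residual form adds the
reconstructed correction to the unit input.

Architecture, per scale `s = 1..S` (all scales use `c` channels, `k×k`
kernels, `L` levels, `B` band convolutions per level):

| layer | shape | role |
|---|---|---|
| embed | `k×k`, 1→c, ReLU | lift the scale's image into feature space |
| fuse (`s<S` only) | `1×1`, 2c→c | merge embedding with upsampled coarser features |
| restrict ×L | `k×k`, c→c, stride 2, ReLU | dyadic decomposition |
| band ×(L·B) | `k×k`, c→c, ReLU | per-level local operators |
| recon ×(L−1) | `k×k`, c→c | coarse-to-fine recombination after 2× upsample |
| lift | `k×k`, c→c | return to the unit's resolution |
| unit output | `k×k`, c→c, **zero-init** | residual correction (identity at start) |
| project | `1×1`, c→1, **zero-init** | restored image, added to the scale input |

Each convolution holds `in·out·k²` weights + `out` biases; the defaults
(S=3, L=4, c=16, B=2, k=3) give 119,907 parameters. Weights use He-normal
initialization with zero biases from a seeded generator, so a (spec, seed)
pair reproduces the network bit-exactly.

Design choices made where the design was genuinely open:

* **Scale coupling.** Scales are processed coarsest→finest with independent
  weights per scale; the finer embedding is fused with the upsampled coarser
  features by channel concatenation + 1×1 convolution.
* **Resampling.** Downsampling between scales is parameter-free 2× average
  pooling, keeping the pyramid a faithful set of downsampled inputs.
  Upsampling is nearest-neighbour ×2 followed by a learned convolution; the
  learned kernel subsumes the smoothing a bilinear kernel would contribute,
  and the operation has an exactly transposable backward pass.
* **Divisibility.** The patch size must be a positive multiple of
  `2^(S−1+L)` so that every pyramid level and every restriction halves an
  even extent; the deepest feature map may legitimately reach 1×1 (with the
  defaults, a 64-pixel patch bottoms out there). Incompatible sizes raise
  before any computation.
* **Output range.** Predictions are not clipped to [0, 1]; clamping is a
  post-processing decision (`enhance_contrast`).
* **Supervision.** Every scale emits a restored image, but only the finest
  is supervised by default; `multiscale_supervision` averages the loss over
  all scales for users who want deep supervision.

## Loss and optimization

`L_total = w_mse·L_MSE + w_ft·L_FT` with defaults 1.0 / 0.5. `L_MSE` is the
mean over images and pixels of the squared difference. `L_FT` is the mean
over images and frequency bins of the magnitude of the difference of the 2D
DFTs, using the **orthonormal** transform so the value is stable against
patch size and comparable in magnitude to the pixel term; the per-bin mean
(rather than a per-image sum) is a convention isolated in one function.
Because the DFT is unitary, the gradient of `L_FT` is the real part of the
inverse transform of the unit-modulus phase field of the difference
spectrum, guarded by a 1e-12 floor at zero magnitude.

Training uses Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8, recorded in the history
metadata), seeded per-epoch shuffling, per-epoch validation of `L_total`,
early stopping (default patience 50 epochs), and best-validation weight
restoration. Only the best and final weights are kept. A non-finite loss
aborts with the epoch and step named. The engine is a compact tape-based
reverse-mode autodiff over float32 numpy arrays implementing exactly the
operator set the model needs; its gradients are validated against central
finite differences in the test suite.

## Data workflow

* **Normalization** is per-stack percentile-clip + min-max to [0, 1];
  defaults (0, 100) are pure min-max. Input and ground truth are normalized
  independently. A constant stack maps to zeros with a warning.
* **Patching** places `P×P` patches on a regular grid with
  `stride = round(P·(1−overlap))`, appending one flush patch at
  `dim − P` per axis when the grid misses the far edge — full coverage with
  no padding, and the printed example holds: a (95, 1024, 1024) stack at
  P=128, 50% overlap gives 15 positions per axis and 21,375 patches. Tiling
  geometry (origins, stride, source shape) travels with the patches so
  stitching needs no side channel.
* **Splitting** applies one seeded permutation identically to inputs and
  ground truth; val/test sizes are `floor(N·ratio)`, the remainder goes to
  train. Shuffling is patch-level, which can place overlapping patches of
  one field of view in different splits — a known leakage caveat for
  overlap > 0; use separate stacks for held-out evaluation where that
  matters (the benchmark in `mrbcr.benchmark` does).
* **Stitching** computes at every pixel the weighted average of covering
  patch values. Windows are separable; `hann` tapers the full patch
  (sample-centered squared sine, nowhere zero), `cosine` ramps only over
  half the overlap extent per edge (e.g. 32-pixel margins, flat 64-wide
  interior at 50% overlap of a 128 patch), `uniform` is constant. A 1e-6
  weight floor guarantees positive accumulated weight at un-overlapped
  borders; the weighted-average normalization makes the floor value
  irrelevant to the round-trip identity `stitch(extract(X)) = X`, which
  holds to 1e-6 for every window and overlap.

## Evaluation metrics

PSNR uses MAX = 1.0 for normalized data and returns an infinity sentinel for
identical images so batch evaluation never aborts. SSIM is implemented in
its global-statistics form (whole-image means, variances, covariance;
C₁ = (0.01·MAX)², C₂ = (0.03·MAX)²); the sliding-window variant common in
other tools is available behind a flag for cross-tool comparison and
delegates to scikit-image. NRMSE divides RMSE by the ground-truth intensity
range and raises on constant ground truth. Entropy quantizes to 8 bits by
rounding (256 levels) and is the Shannon entropy of the histogram, in
[0, 8] bits; image sets are stratified at 5 bits (strict `<` = sparse). FRC
uses shells of width one frequency pixel on centered integer coordinates,
takes the real part of the normalized cross-spectrum per shell, and marks
empty shells undefined rather than interpolating. Set-level aggregation
reports per-shell mean/std and the restoration-to-input difference curve.

## Synthetic data generator

The generator emulates paired exposure-series data (denoise task) and
blurred/sharp pairs (deconvolve task). Clean scenes are Gaussian spots
(amplitude 0.2–1, width 1–3 px), rasterized random quadratic filaments
(width 1–2 px after light smoothing), or elliptical cell rims, on a zero
background, min-max normalized. Degradation is the standard fluorescence
forward model: optional Gaussian PSF blur (deconvolve only — for the
denoise task input and target share the scene's intrinsic blur), Poisson
shot noise at the condition's photon budget, additive Gaussian read noise
(σ = 0.02), clipping at zero, min-max normalization. Default budgets
GT/C1/C2/C3 = 1000/100/30/10 expected photons at unit intensity produce a
monotone SNR ladder (≈33/29/26 dB input PSNR on mid-density spot scenes)
mirroring a medium/weak/extremely-weak illumination series. Density
calibrates sparsity by construction: 2 spots on 128² measure ≈0.3 bits,
200 spots ≈5.5 bits, so the 5-bit threshold separates them; the suite
asserts this. An infinite photon budget short-circuits the Poisson stage,
giving the noiseless identity limit used in tests.

What the generator does **not** model: realistic optical PSFs
(Gibson–Lanni), structured illumination, detector fixed-pattern noise,
sample motion, or 3D effects. Passing tests on this data show the
architecture and pipeline restore signal under Poisson–Gaussian
degradation; they do not certify performance on any particular instrument
or specimen.

## Benchmark experiment and problem sizes

`mrbcr.benchmark.denoise_benchmark` is the package's end-to-end check,
sized to run in a few minutes on one CPU core: 12 training scenes at 128²
(6 sparse spot images at density 3, 6 dense filament images at density 60),
degraded to the C2 budget, tiled into 108 64×64 patch pairs (90/10
train/val), default model, 500 Adam steps at batch 8; evaluation on 8
held-out full images from fresh seeds. With seed 1 it measures a +7.0 dB
mean PSNR gain (25.6 → 32.5 dB), SSIM 0.77 → 0.96, sparse scenes restoring
≈21 dB above dense ones, entropy–PSNR correlation ≈ −0.996, and a positive
FRC improvement band spanning ≈49 contiguous mid-frequency shells. The
expressivity smoke test overfits 4 structured noisy→clean 32² pairs with a
reduced spec (S=2, L=2, c=16) below 1e-3 total loss within 2000 steps;
structured scenes are used because a translation-invariant CNN cannot
memorize unstructured per-pixel noise at any feasible step count.

## Known limitations

* Single-channel 2D only; no axial (3D) context, no time-lapse semantics,
  no HDF5/OME-TIFF/Zarr I/O.
* The numpy training loop is single-device and unaccelerated; it is sized
  for patch-scale experiments, not for full benchmark-scale training runs.
* Global SSIM (the default) saturates differently from windowed SSIM;
  comparisons against tools that window should use the flag.
* Patch-level split shuffling can leak overlapping content between splits
  (see above).
* FRC physical-frequency labeling requires a pixel size; shells are always
  defined in frequency pixels.
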