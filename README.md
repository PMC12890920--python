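# mrbcr

Denoising and deconvolution of fluorescence light-microscopy images with a
lightweight **multi-resolution residual BCR network** (m-rBCR), plus the
complete data workflow around it — normalize → patch → train → predict →
stitch — and a quantitative evaluation suite (PSNR, SSIM, RMSE/NRMSE, image
entropy, Fourier Ring Correlation).

It is aimed at microscopists and image-analysis developers who have paired
acquisitions — a low-SNR exposure with a high-SNR counterpart, or a blurred
widefield image with a sharper super-resolution reference — and want to train
a compact supervised restoration model on them without GPU-scale resources.

## The model

The building block is a convolutional realization of the
Beylkin–Coifman–Rokhlin (BCR) nonstandard wavelet form of an integral
operator. A **residual BCR unit** restricts a feature map through *L* dyadic
levels with stride-2 convolutions, applies a small stack of local *band*
convolutions at every level, recombines the levels coarse-to-fine
(2× upsampling + convolution), and adds the result back to its input. Its
output convolution is zero-initialized, so the unit — and the whole network —
is exactly the identity map before training: optimization starts from the
"do nothing" restoration.

One unit wrapped with an input embedding and a linear output projection forms
a single-resolution restoration block (s-rBCR). The multi-resolution network
(m-rBCR) runs one block per scale of an input pyramid (2× average-pool
downsampling, *S* scales), coarsest first, fusing each scale's embedding with
the upsampled features of the next-coarser scale. Every scale emits a restored
image; the finest is the prediction. The default configuration
(*S* = 3, *L* = 4, 16 channels, 2 band convolutions, 3×3 kernels) has
**119,907 trainable parameters** — orders of magnitude fewer than U-Net-class
restoration models.

Training minimizes a combined objective

```
L_total = 1.0 · L_MSE + 0.5 · L_FT
```

where `L_MSE` is the mean squared pixel error and `L_FT` is the mean magnitude
of the difference of the 2D discrete Fourier transforms (orthonormal
convention) — the spectral term penalizes deviations uniformly across
frequencies. Optimization is Adam (lr 0.001, batch 32 by default, up to 2000
epochs) with per-epoch validation, early stopping, and best-weights
restoration.

## Worked example

Simulate a paired weak-exposure dataset, train briefly, restore fresh images,
and evaluate (the built-in generator renders fluorescence-like scenes and
degrades them with Poisson shot noise + Gaussian read noise):

```sh
mrbcr simulate --structure spots --n-images 8 --image-size 128 --density 40 \
               --patch-size 64 --condition C2 --seed 0 --out spots_c2.npz
# simulate: wrote spots_c2.npz with splits train/val/test = (58, 7, 7)

mrbcr train --data spots_c2.npz --config train.yml --max-steps 200 --out model.npz
# epoch   24  train 0.002202  val 0.002819  lr 0.001
# train: 25 epochs, best val loss 0.002819 at epoch 24; wrote model.npz

mrbcr predict --weights model.npz --input noisy.tif --patch-size 64 \
              --overlap 0.5 --window hann --out restored.tif
# predict: restored 18 patches (batch size 32)
# predict: stitched (hann window) and wrote restored.tif

mrbcr evaluate --pred restored.tif --gt gt.tif --input noisy.tif --out report.tsv
# evaluate: mean PSNR 36.03 dB, mean SSIM 0.9641; wrote report.tsv
```

For reference, evaluating the degraded input against the same ground truth
gives 29.45 dB / 0.9126 — the 200-step model already recovers ≈6.6 dB of PSNR
and lifts SSIM by 0.05 on scenes it never saw. `report.tsv` holds one row per
image (PSNR, SSIM, RMSE, NRMSE, entropy, sparse flag: entropy < 5 bits marks
a sparse scene) plus a shell-wise FRC table when `--input` is given.

The same workflow applies to real data: `mrbcr prepare` turns single-channel
TIFF stacks into normalized 128×128 patch datasets (50% overlap by default,
0.8/0.1/0.1 train/val/test split), and `mrbcr predict` stitches restored
patches back seamlessly with uniform, cosine (margin-tapered), or Hann
blending windows.

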