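"""Batched prediction on patch sets, windowed blending, and stitching back
into full images.

Stitching computes at every pixel the weighted average of all patch values
covering it, with separable blend windows (uniform, Hann, or margin-only
raised-cosine). Because the weights form a normalized partition at each
pixel, unmodified crops stitch back to the exact source, and tapered
windows suppress seam artifacts on modified (restored) patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageStack
from .model import MRBCR
from .preprocess import PatchSet, normalize_stack

__all__ = [
    "BlendWindow",
    "predict",
    "make_window",
    "stitch_patches",
    "enhance_contrast",
]

_WEIGHT_FLOOR = 1e-6


@dataclass
class BlendWindow:
    """A separable nonnegative patch weighting used for stitch blending."""

    kind: str
    weights: np.ndarray  # (P, P), all >= the small floor

    def __post_init__(self):
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("window weights must be a square 2D array")
        if (self.weights < _WEIGHT_FLOOR).any():
            raise ValueError("window weights fell below the positivity floor")


def predict(model: MRBCR, patches: PatchSet, batch_size: int = 32) -> PatchSet:
    """Run the model over a patch set in minibatches.

    Output patches stay aligned one-to-one with the input (same metadata);
    the result is independent of ``batch_size`` up to float tolerance.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    arr = np.asarray(patches.patches, dtype=np.float32)
    out = np.empty_like(arr)
    for i in range(0, len(arr), batch_size):
        out[i : i + batch_size] = model.predict(arr[i : i + batch_size])
    if not np.isfinite(out).all():
        raise RuntimeError("model produced non-finite patch values")
    return PatchSet(patches=out, meta=patches.meta)


def _hann_1d(p: int) -> np.ndarray:
    # squared-sine taper over the full patch, sample-centered so no weight is 0
    i = np.arange(p) + 0.5
    return np.sin(np.pi * i / p) ** 2


def _cosine_margin_1d(p: int, overlap_fraction: float) -> np.ndarray:
    # raised-cosine ramp over half the overlap extent per edge, flat interior
    m = int(round(overlap_fraction * p / 2))
    w = np.ones(p)
    if m > 0:
        i = np.arange(m) + 0.5
        ramp = np.sin(0.5 * np.pi * i / m) ** 2
        w[:m] = ramp
        w[-m:] = ramp[::-1]
    return w


def make_window(patch_size: int, kind: str = "hann", overlap_fraction: float = 0.5) -> BlendWindow:
    """Build a separable blend window.

    'uniform' is all ones; 'hann' tapers over the whole patch; 'cosine'
    ramps only over the overlap margin (overlap_fraction * patch_size / 2
    pixels per edge, e.g. 32-pixel margins with a flat 64-wide interior at
    50% overlap of a 128 patch) and is flat elsewhere. All weights are
    clamped to a small positive floor so accumulated stitch weights never
    vanish.
    """
    if patch_size < 2:
        raise ValueError("patch_size must be >= 2")
    if kind == "uniform":
        w1 = np.ones(patch_size)
    elif kind == "hann":
        w1 = _hann_1d(patch_size)
    elif kind == "cosine":
        w1 = _cosine_margin_1d(patch_size, overlap_fraction)
    else:
        raise ValueError(f"unknown window kind '{kind}'")
    weights = np.maximum(np.outer(w1, w1), _WEIGHT_FLOOR)
    return BlendWindow(kind=kind, weights=weights)


def stitch_patches(patches: PatchSet, window: BlendWindow | None = None) -> ImageStack:
    """Reassemble a patch set into its source-shaped stack.

    Every pixel receives the weighted average of all patch values covering
    it: out(x) = sum_i w_i(x) patch_i(x) / sum_i w_i(x). For unmodified
    crops this reproduces the source to float precision for any window.
    """
    meta = patches.meta
    P = meta.patch_size
    if window is None:
        window = make_window(P, meta.window_kind, meta.overlap_fraction)
    if window.weights.shape != (P, P):
        raise ValueError(
            f"window shape {window.weights.shape} does not match patch size {P}"
        )
    N, H, W = meta.source_shape
    acc = np.zeros((N, H, W), dtype=np.float64)
    wacc = np.zeros((N, H, W), dtype=np.float64)
    w = window.weights
    for patch, (n, r, c) in zip(patches.patches, meta.origins):
        acc[n, r : r + P, c : c + P] += w * patch
        wacc[n, r : r + P, c : c + P] += w
    if (wacc <= 0).any():
        raise RuntimeError("zero accumulated stitch weight: patch grid does not cover source")
    return ImageStack((acc / wacc).astype(np.float32))


def enhance_contrast(stack: ImageStack, low: float = 0.0, high: float = 100.0) -> ImageStack:
    """Optional output contrast stretch: percentile-clip then rescale to [0, 1]."""
    if not low < high:
        raise ValueError(f"invalid percentile range ({low}, {high})")
    return normalize_stack(stack, low, high)
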