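"""Raw stacks to training-ready data: intensity normalization, overlapping
patch extraction with exact-reassembly metadata, and paired train/val/test
splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import DatasetSplit, ImageStack, _atomic_save

__all__ = [
    "PatchGridMeta",
    "PatchSet",
    "normalize_stack",
    "patch_grid",
    "extract_patches",
    "split_dataset",
    "save_patchset",
    "load_patchset",
]


@dataclass
class PatchGridMeta:
    """Geometry of a patch tiling, sufficient to reassemble the source.

    ``origins`` lists (slice_index, row, col) top-left corners, 0-based with
    half-open patch extents, in row-major order within each slice. The grid
    places patches at multiples of ``stride`` and appends one flush patch
    anchored at ``dim - patch_size`` per axis whenever the regular grid does
    not already reach the far edge, so the union of extents covers every
    pixel.
    """

    source_shape: tuple[int, int, int]
    patch_size: int
    stride: int
    origins: list[tuple[int, int, int]]
    overlap_fraction: float = 0.0
    window_kind: str = "uniform"

    def __post_init__(self):
        _, H, W = self.source_shape
        for (_, r, c) in self.origins:
            if r + self.patch_size > H or c + self.patch_size > W:
                raise ValueError("patch origin extends beyond the source image")


@dataclass
class PatchSet:
    """A batch of square patches plus its tiling geometry."""

    patches: np.ndarray  # (M, P, P)
    meta: PatchGridMeta = field(repr=False)

    def __post_init__(self):
        self.patches = np.asarray(self.patches)
        if len(self.patches) != len(self.meta.origins):
            raise ValueError(
                f"{len(self.patches)} patches but {len(self.meta.origins)} origins"
            )


def _axis_positions(dim: int, patch_size: int, stride: int) -> list[int]:
    """Regular grid 0, stride, 2*stride, ... plus a flush position at
    dim - patch_size when the grid does not reach the far edge."""
    last = dim - patch_size
    positions = list(range(0, last + 1, stride))
    if positions[-1] != last:
        positions.append(last)
    return positions


def normalize_stack(
    stack: ImageStack, clip_low: float = 0.0, clip_high: float = 100.0
) -> ImageStack:
    """Percentile-clip then min-max scale a stack to [0, 1].

    With the default (0, 100) percentiles this is exact per-stack min-max
    scaling. Narrower percentiles clip outliers before scaling. A constant
    stack maps to all zeros with a warning.
    """
    if not (0 <= clip_low < clip_high <= 100):
        raise ValueError(f"invalid percentile range ({clip_low}, {clip_high})")
    pix = stack.pixels.astype(np.float64)
    lo, hi = np.percentile(pix, [clip_low, clip_high])
    if hi == lo:
        warnings.warn("constant stack: normalization yields all zeros", stacklevel=2)
        return ImageStack(np.zeros_like(pix, dtype=np.float32), stack.pixel_size)
    out = (np.clip(pix, lo, hi) - lo) / (hi - lo)
    return ImageStack(out.astype(np.float32), stack.pixel_size)


def patch_grid(
    source_shape: tuple[int, int, int],
    patch_size: int,
    overlap_fraction: float = 0.5,
    window_kind: str = "uniform",
) -> PatchGridMeta:
    """Compute the tiling geometry without touching pixel data.

    stride = round(patch_size * (1 - overlap_fraction)), floored at 1.
    """
    N, H, W = source_shape
    if not 0 <= overlap_fraction < 1:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if patch_size > min(H, W):
        raise ValueError(
            f"patch_size {patch_size} exceeds image extent {(H, W)}"
        )
    stride = max(1, round(patch_size * (1.0 - overlap_fraction)))
    rows = _axis_positions(H, patch_size, stride)
    cols = _axis_positions(W, patch_size, stride)
    origins = [(n, r, c) for n in range(N) for r in rows for c in cols]
    return PatchGridMeta(
        source_shape=(N, H, W),
        patch_size=patch_size,
        stride=stride,
        origins=origins,
        overlap_fraction=float(overlap_fraction),
        window_kind=window_kind,
    )


def extract_patches(
    stack: ImageStack, patch_size: int, overlap_fraction: float = 0.5
) -> PatchSet:
    """Tile a stack into partially overlapping square patches.

    Patch values are exact copies of source pixels; the returned metadata
    guarantees full coverage of every slice (regular grid positions plus a
    flush edge patch per axis when needed).
    """
    meta = patch_grid(stack.shape, patch_size, overlap_fraction)
    P = patch_size
    pix = stack.pixels
    patches = np.empty((len(meta.origins), P, P), dtype=pix.dtype)
    for i, (n, r, c) in enumerate(meta.origins):
        patches[i] = pix[n, r : r + P, c : c + P]
    return PatchSet(patches=patches, meta=meta)


def split_dataset(
    inputs: PatchSet,
    gts: PatchSet,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle paired patches once and partition into train/val/test.

    A single seeded permutation is applied identically to inputs and ground
    truth, so pairing is preserved. Validation and test sizes are
    floor(N * ratio); the remainder goes to train.
    """
    if inputs.patches.shape != gts.patches.shape:
        raise ValueError(
            f"input patches {inputs.patches.shape} and GT patches "
            f"{gts.patches.shape} are misaligned"
        )
    if abs(sum(ratios) - 1.0) > 1e-8:
        raise ValueError(f"split ratios {ratios} must sum to 1")
    n = len(inputs.patches)
    n_val = int(np.floor(n * ratios[1]))
    n_test = int(np.floor(n * ratios[2]))
    n_train = n - n_val - n_test
    perm = np.random.default_rng(seed).permutation(n)
    x = np.asarray(inputs.patches, dtype=np.float32)[perm]
    y = np.asarray(gts.patches, dtype=np.float32)[perm]
    return DatasetSplit(
        x_train=x[:n_train],
        y_train=y[:n_train],
        x_val=x[n_train : n_train + n_val],
        y_val=y[n_train : n_train + n_val],
        x_test=x[n_train + n_val :],
        y_test=y[n_train + n_val :],
    )


def save_patchset(path, patchset: PatchSet) -> None:
    """Write patches together with their tiling geometry to NPZ, so that
    stitching later needs no side channel."""
    meta = patchset.meta
    payload = {
        "patches": np.asarray(patchset.patches),
        "origins": np.asarray(meta.origins, dtype=np.int64).reshape(-1, 3),
        "source_shape": np.asarray(meta.source_shape, dtype=np.int64),
        "patch_size": np.int64(meta.patch_size),
        "stride": np.int64(meta.stride),
        "overlap_fraction": np.float64(meta.overlap_fraction),
        "window_kind": np.frombuffer(meta.window_kind.encode(), dtype=np.uint8),
    }
    _atomic_save(Path(path), lambda tmp: np.savez(tmp, **payload))


def load_patchset(path) -> PatchSet:
    """Read a patch set written by :func:`save_patchset`."""
    with np.load(path) as npz:
        meta = PatchGridMeta(
            source_shape=tuple(int(v) for v in npz["source_shape"]),
            patch_size=int(npz["patch_size"]),
            stride=int(npz["stride"]),
            origins=[tuple(int(v) for v in row) for row in npz["origins"]],
            overlap_fraction=float(npz["overlap_fraction"]),
            window_kind=bytes(npz["window_kind"]).decode(),
        )
        return PatchSet(patches=npz["patches"], meta=meta)
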