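"""Batched prediction, blend windows, stitching, and contrast enhancement."""

import numpy as np
import pytest

from mrbcr.io import ImageStack
from mrbcr.model import ModelSpec, build_model
from mrbcr.postprocess import (
    enhance_contrast,
    make_window,
    predict,
    stitch_patches,
)
from mrbcr.preprocess import extract_patches, PatchSet


class TestPredict:
    def test_identity_at_init_passes_patches_through(self, rng):
        model = build_model(ModelSpec(scales=2, bcr_levels=2, base_channels=8), seed=0)
        stack = ImageStack(rng.uniform(0, 1, (1, 64, 64)).astype(np.float32))
        patches = extract_patches(stack, 16, 0.5)
        out = predict(model, patches, batch_size=8)
        np.testing.assert_array_equal(out.patches, patches.patches)
        assert out.meta is patches.meta

    def test_batch_size_independence_on_odd_count(self, rng):
        model = build_model(ModelSpec(scales=2, bcr_levels=2, base_channels=8), seed=0)
        for p in model.params:
            if not p.data.any():
                p.data = np.random.default_rng(5).normal(0, 0.05, p.data.shape).astype(np.float32)
        stack = ImageStack(rng.uniform(0, 1, (1, 16 * 33, 16)).astype(np.float32))
        patches = extract_patches(stack, 16, 0.0)
        assert len(patches.patches) == 33
        one = predict(model, patches, batch_size=1)
        many = predict(model, patches, batch_size=32)
        np.testing.assert_allclose(one.patches, many.patches, atol=1e-5)

    def test_invalid_batch_size(self, rng):
        model = build_model(ModelSpec(scales=1, bcr_levels=1, base_channels=4), seed=0)
        stack = ImageStack(rng.uniform(0, 1, (1, 16, 16)).astype(np.float32))
        with pytest.raises(ValueError, match="batch_size"):
            predict(model, extract_patches(stack, 16, 0.0), batch_size=0)


class TestMakeWindow:
    def test_uniform_is_all_ones(self):
        win = make_window(4, "uniform")
        np.testing.assert_array_equal(win.weights, np.ones((4, 4)))

    def test_hann_center_max_and_symmetric(self):
        win = make_window(32, "hann")
        w = win.weights
        assert w.max() == w[15:17, 15:17].max()
        np.testing.assert_allclose(w, w[::-1, :], atol=1e-12)
        np.testing.assert_allclose(w, w[:, ::-1], atol=1e-12)
        assert (w >= 1e-6).all()

    def test_cosine_margin_against_closed_form(self):
        # overlap 0.5, P=128: 32-pixel tapered margins, flat 64-wide interior
        win = make_window(128, "cosine", overlap_fraction=0.5)
        w1 = win.weights[64, :] / win.weights[64, 64]
        m = 32
        i = np.arange(m) + 0.5
        ramp = np.sin(0.5 * np.pi * i / m) ** 2
        np.testing.assert_allclose(w1[:32], ramp, atol=1e-10)
        np.testing.assert_allclose(w1[32:96], 1.0)
        np.testing.assert_allclose(w1, w1[::-1], atol=1e-12)

    def test_cosine_flat_interior(self):
        win = make_window(128, "cosine", overlap_fraction=0.25)
        w1 = win.weights[64, :]
        assert np.all(w1[16:112] == w1[64])  # flat interior of width 96

    def test_separability(self):
        win = make_window(16, "hann")
        w1 = np.sqrt(np.diag(win.weights))
        np.testing.assert_allclose(win.weights, np.outer(w1, w1), rtol=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown window"):
            make_window(16, "triangular")


class TestStitch:
    @pytest.mark.parametrize("kind", ["uniform", "cosine", "hann"])
    @pytest.mark.parametrize("overlap", [0.25, 0.5, 0.75])
    def test_round_trip_identity(self, rng, kind, overlap):
        # includes a non-divisible-stride shape exercising flush patches
        stack = ImageStack(rng.uniform(0, 1, (2, 50, 38)).astype(np.float32))
        patches = extract_patches(stack, 16, overlap)
        win = make_window(16, kind, overlap)
        out = stitch_patches(patches, win)
        np.testing.assert_allclose(out.pixels, stack.pixels, atol=1e-6)

    def test_overlapping_constants_average(self):
        from mrbcr.preprocess import PatchGridMeta

        meta = PatchGridMeta(
            source_shape=(1, 4, 6), patch_size=4, stride=2,
            origins=[(0, 0, 0), (0, 0, 2)],
        )
        patches = PatchSet(
            patches=np.stack([np.zeros((4, 4)), np.ones((4, 4))]), meta=meta
        )
        out = stitch_patches(patches, make_window(4, "uniform"))
        np.testing.assert_allclose(out.pixels[0, :, 2:4], 0.5)
        np.testing.assert_allclose(out.pixels[0, :, :2], 0.0)
        np.testing.assert_allclose(out.pixels[0, :, 4:], 1.0)

    def test_hann_blending_suppresses_seams(self, rng):
        # randomly perturbed patches: tapered blending must not create
        # boundary jumps larger than the interior gradients
        stack = ImageStack(rng.uniform(0.4, 0.6, (1, 64, 64)).astype(np.float32))
        patches = extract_patches(stack, 16, 0.5)
        perturbed = patches.patches + rng.normal(0, 0.05, (len(patches.patches), 1, 1)).astype(
            np.float32
        )
        noisy = PatchSet(patches=perturbed, meta=patches.meta)
        out = stitch_patches(noisy, make_window(16, "hann", 0.5)).pixels[0]
        boundary_cols = [15, 16, 31, 32, 47, 48]
        grad_cols = np.abs(np.diff(out, axis=1))
        seam = grad_cols[:, [c for c in boundary_cols if c < grad_cols.shape[1]]].max()
        interior = grad_cols.max()
        assert seam <= interior + 1e-9

    def test_output_is_convex_combination(self, rng):
        stack = ImageStack(rng.uniform(0, 1, (1, 32, 32)).astype(np.float32))
        patches = extract_patches(stack, 16, 0.5)
        shifted = PatchSet(patches=patches.patches + 0.1, meta=patches.meta)
        out = stitch_patches(shifted, make_window(16, "hann", 0.5))
        assert out.pixels.min() >= shifted.patches.min() - 1e-6
        assert out.pixels.max() <= shifted.patches.max() + 1e-6

    def test_window_size_mismatch_rejected(self, rng):
        stack = ImageStack(rng.uniform(0, 1, (1, 32, 32)).astype(np.float32))
        patches = extract_patches(stack, 16, 0.5)
        with pytest.raises(ValueError, match="window"):
            stitch_patches(patches, make_window(8, "uniform"))


class TestEnhanceContrast:
    def test_identity_on_full_range_image(self, rng):
        img = rng.uniform(0, 1, (1, 32, 32))
        img[0, 0, 0], img[0, 0, 1] = 0.0, 1.0
        out = enhance_contrast(ImageStack(img), 0, 100)
        np.testing.assert_allclose(out.pixels, img, atol=1e-7)

    def test_hot_pixel_clipped(self, rng):
        img = rng.uniform(0, 0.5, (1, 100, 100))
        img[0, 50, 50] = 1e6
        out = enhance_contrast(ImageStack(img), 0, 99)
        assert out.pixels[0, 50, 50] == 1.0
        assert np.sum(out.pixels == 1.0) > 1  # clipped, not lone max

    def test_matches_percentile_oracle(self, rng):
        from test_preprocess import brute_force_normalize

        img = rng.normal(5, 2, (2, 21, 17))
        out = enhance_contrast(ImageStack(img), 1, 99)
        np.testing.assert_allclose(
            out.pixels, brute_force_normalize(img, 1, 99), atol=1e-6
        )
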