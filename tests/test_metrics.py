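"""Scalar quality metrics, entropy stratification, and FRC — each checked
against independent direct-summation oracles."""

import math

import numpy as np
import pytest

from mrbcr.metrics import (
    MetricsConfig,
    entropy,
    evaluate_pairs,
    frc_aggregate,
    frc_curve,
    nrmse,
    psnr,
    ssim,
    stratify_by_entropy,
    write_report,
)

CFG = MetricsConfig()


# ------------------------------------------------------------------ oracles


def oracle_mse(pred, gt):
    return math.fsum(
        (float(p) - float(g)) ** 2 for p, g in zip(pred.ravel(), gt.ravel())
    ) / pred.size


def oracle_psnr(pred, gt, max_val=1.0):
    return 10.0 * math.log10(max_val**2 / oracle_mse(pred, gt))


def oracle_ssim(pred, gt, max_val=1.0):
    n = pred.size
    mu_p = math.fsum(map(float, pred.ravel())) / n
    mu_g = math.fsum(map(float, gt.ravel())) / n
    var_p = math.fsum((float(v) - mu_p) ** 2 for v in pred.ravel()) / n
    var_g = math.fsum((float(v) - mu_g) ** 2 for v in gt.ravel()) / n
    cov = math.fsum(
        (float(p) - mu_p) * (float(g) - mu_g) for p, g in zip(pred.ravel(), gt.ravel())
    ) / n
    c1, c2 = (0.01 * max_val) ** 2, (0.03 * max_val) ** 2
    return ((2 * mu_g * mu_p + c1) * (2 * cov + c2)) / (
        (mu_g**2 + mu_p**2 + c1) * (var_g + var_p + c2)
    )


def oracle_frc(a, b):
    """Direct-summation FRC: explicit DFT matrix, loop over all frequency
    pairs, bin by centered radius."""
    p = a.shape[0]
    j = np.arange(p)
    F = np.exp(-2j * np.pi * np.outer(j, j) / p)
    fa = F @ a.astype(complex) @ F
    fb = F @ b.astype(complex) @ F
    rmax = p // 2
    cross = np.zeros(rmax + 1)
    pow_a = np.zeros(rmax + 1)
    pow_b = np.zeros(rmax + 1)
    for u in range(p):
        for v in range(p):
            uu = u if u <= p // 2 else u - p
            vv = v if v <= p // 2 else v - p
            r = int(np.floor(np.sqrt(uu * uu + vv * vv) + 0.5))
            if r > rmax:
                continue
            cross[r] += (fa[u, v] * np.conj(fb[u, v])).real
            pow_a[r] += abs(fa[u, v]) ** 2
            pow_b[r] += abs(fb[u, v]) ** 2
    return cross / np.sqrt(pow_a * pow_b)


# -------------------------------------------------------------------- PSNR


class TestPSNR:
    def test_mse_001_gives_20db(self):
        gt = np.zeros((10, 10))
        pred = gt + 0.1  # MSE exactly 0.01
        assert psnr(pred, gt, CFG) == pytest.approx(20.0, abs=1e-12)

    def test_identical_images_give_inf_sentinel(self, rng):
        x = rng.uniform(size=(8, 8))
        assert psnr(x, x, CFG) == float("inf")

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            a, b = rng.uniform(size=(2, 16, 16))
            assert psnr(a, b, CFG) == pytest.approx(oracle_psnr(a, b), rel=1e-10)

    def test_pixel_permutation_invariant(self, rng):
        a, b = rng.uniform(size=(2, 16, 16))
        perm = rng.permutation(256)
        assert psnr(a.ravel()[perm], b.ravel()[perm], CFG) == pytest.approx(
            psnr(a, b, CFG), rel=1e-12
        )


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        x = rng.uniform(size=(16, 16))
        assert ssim(x, x, CFG) == pytest.approx(1.0, abs=1e-12)

    def test_constant_images_closed_form(self):
        # constant 0.25 vs 0.5: variance factor is exactly C2/C2 = 1, the
        # luminance factor is (2*0.125 + C1) / (0.3125 + C1)
        pred = np.full((8, 8), 0.25)
        gt = np.full((8, 8), 0.5)
        c1 = (0.01) ** 2
        expected = (2 * 0.25 * 0.5 + c1) / (0.25**2 + 0.5**2 + c1)
        assert ssim(pred, gt, CFG) == pytest.approx(expected, rel=1e-12)

    def test_anticorrelated_pair_is_negative(self, rng):
        gt = rng.uniform(size=(16, 16))
        pred = 1.0 - gt  # covariance strictly negative
        assert ssim(pred, gt, CFG) < 0

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            a, b = rng.uniform(size=(2, 16, 16))
            assert ssim(a, b, CFG) == pytest.approx(oracle_ssim(a, b), rel=1e-10)

    def test_windowed_variant_agrees_with_reference_library(self, rng):
        from skimage.metrics import structural_similarity

        a, b = rng.uniform(size=(2, 32, 32))
        ours = ssim(a, b, CFG, windowed=True)
        theirs = structural_similarity(b, a, data_range=1.0, gaussian_weights=False)
        assert ours == pytest.approx(theirs, rel=1e-12)


class TestNRMSE:
    def test_identity_gives_zero(self, rng):
        x = rng.uniform(size=(8, 8))
        assert nrmse(x, x) == (0.0, 0.0)

    def test_constant_offset_unit_range(self):
        gt = np.linspace(0, 1, 64).reshape(8, 8)  # range exactly 1
        pred = gt + 0.1
        r, nr = nrmse(pred, gt)
        assert r == pytest.approx(0.1, rel=1e-12)
        assert nr == pytest.approx(0.1, rel=1e-12)

    def test_matches_oracle(self, rng):
        a, b = rng.uniform(size=(2, 16, 16))
        r, nr = nrmse(a, b)
        assert r == pytest.approx(math.sqrt(oracle_mse(a, b)), rel=1e-10)
        assert nr == pytest.approx(r / (b.max() - b.min()), rel=1e-12)

    def test_constant_gt_rejected(self, rng):
        with pytest.raises(ValueError, match="range"):
            nrmse(rng.uniform(size=(8, 8)), np.full((8, 8), 0.5))


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(np.full((16, 16), 0.3)) == 0.0

    def test_uniform_256_levels_eight_bits(self):
        img = np.arange(256).reshape(16, 16) / 255.0
        assert entropy(img) == pytest.approx(8.0, abs=1e-12)

    def test_half_zero_half_one_is_one_bit(self):
        img = np.zeros((16, 16))
        img[:8] = 1.0
        assert entropy(img) == pytest.approx(1.0, abs=1e-12)

    def test_out_of_range_clipped_with_warning(self):
        img = np.full((4, 4), 1.5)
        with pytest.warns(UserWarning, match="clipping"):
            assert entropy(img) == 0.0

    def test_bounded_in_zero_eight(self, rng):
        for _ in range(5):
            e = entropy(rng.uniform(size=(16, 16)))
            assert 0.0 <= e <= 8.0

    def test_permutation_invariant(self, rng):
        img = rng.uniform(size=(16, 16))
        perm = rng.permutation(256)
        assert entropy(img.ravel()[perm].reshape(16, 16)) == entropy(img)


class TestStratify:
    def test_exemplar_entropies_split_one_each(self):
        # a markedly sparse image and a markedly dense one land on opposite
        # sides of the 5-bit threshold
        sparse_grp, dense_grp, _ = stratify_by_entropy(
            np.array([1.62, 6.49]), {"psnr": np.array([30.0, 20.0])}
        )
        assert (sparse_grp.count, dense_grp.count) == (1, 1)
        assert sparse_grp.mean["psnr"] == 30.0
        assert dense_grp.mean["psnr"] == 20.0

    def test_empty_dense_group_flagged(self):
        sparse_grp, dense_grp, _ = stratify_by_entropy(
            np.array([1.0, 2.0]), {"psnr": np.array([30.0, 31.0])}
        )
        assert dense_grp.count == 0
        assert math.isnan(dense_grp.mean["psnr"])

    def test_group_means_match_hand_average(self):
        ents = np.array([1.0, 2.0, 6.0, 7.0])
        vals = np.array([10.0, 20.0, 30.0, 40.0])
        sparse_grp, dense_grp, per_image = stratify_by_entropy(ents, {"m": vals})
        assert sparse_grp.mean["m"] == pytest.approx(15.0)
        assert dense_grp.mean["m"] == pytest.approx(35.0)
        assert len(per_image) == 4
        assert per_image[2] == (6.0, {"m": 30.0})

    def test_threshold_is_strict_less_for_sparse(self):
        sparse_grp, dense_grp, _ = stratify_by_entropy(
            np.array([5.0]), {"m": np.array([1.0])}
        )
        assert (sparse_grp.count, dense_grp.count) == (0, 1)


class TestFRC:
    def test_self_correlation_is_one_everywhere(self, rng):
        img = rng.uniform(size=(32, 32))
        curve = frc_curve(img, img)
        valid = np.isfinite(curve.values)
        np.testing.assert_allclose(curve.values[valid], 1.0, atol=1e-9)

    def test_dc_shell_is_one_for_equal_mean_images(self, rng):
        a = rng.uniform(0.2, 0.8, size=(16, 16))
        b = rng.uniform(0.2, 0.8, size=(16, 16))
        b += a.mean() - b.mean()
        assert frc_curve(a, b).values[0] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_decorrelates_high_shells(self, rng):
        a = rng.standard_normal((64, 64))
        b = rng.standard_normal((64, 64))
        curve = frc_curve(a, b).values
        high = curve[8:]
        # under the null, |FRC| ~ 1/sqrt(n_shell); allow the usual 3-sigma
        assert np.mean(np.abs(high) < 3.0 / np.sqrt(8)) > 0.8

    def test_matches_direct_summation_oracle(self, rng):
        a, b = rng.uniform(size=(2, 16, 16))
        curve = frc_curve(a, b)
        np.testing.assert_allclose(curve.values, oracle_frc(a, b), rtol=1e-8)

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            frc_curve(rng.uniform(size=(8, 16)), rng.uniform(size=(8, 16)))

    def test_physical_frequency_axis(self, rng):
        img = rng.uniform(size=(16, 16))
        curve = frc_curve(img, img, pixel_size=100.0)  # nm/pixel
        freqs = curve.frequencies()
        assert freqs[0] == 0.0
        assert freqs[-1] == pytest.approx(8 / (16 * 100.0))


class TestFRCAggregate:
    def test_identity_prediction_set(self, rng):
        gt = rng.uniform(size=(3, 16, 16))
        noisy = gt + rng.normal(0, 0.2, gt.shape)
        pred_curve, input_curve, diff = frc_aggregate(gt, noisy, gt)
        valid = np.isfinite(pred_curve.values)
        np.testing.assert_allclose(pred_curve.values[valid], 1.0, atol=1e-9)
        np.testing.assert_allclose(
            diff[valid], 1.0 - input_curve.values[valid], atol=1e-9
        )

    def test_single_image_set_zero_std(self, rng):
        gt = rng.uniform(size=(1, 16, 16))
        pred = gt + rng.normal(0, 0.1, gt.shape)
        pred_curve, _, _ = frc_aggregate(pred, pred, gt)
        np.testing.assert_allclose(pred_curve.std, 0.0, atol=1e-12)

    def test_misaligned_sets_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            frc_aggregate(
                rng.uniform(size=(2, 8, 8)),
                rng.uniform(size=(3, 8, 8)),
                rng.uniform(size=(2, 8, 8)),
            )


class TestReport:
    def test_report_rows_and_frc_table(self, tmp_path, rng):
        gt = rng.uniform(size=(3, 16, 16))
        pred = np.clip(gt + rng.normal(0, 0.05, gt.shape), 0, 1)
        per_image = evaluate_pairs(pred, gt)
        pred_curve, _, _ = frc_aggregate(pred, pred, gt)
        out = tmp_path / "report.tsv"
        write_report(out, per_image, frc_table=pred_curve)
        lines = out.read_text().strip().splitlines()
        assert lines[0].split("\t") == [
            "id", "psnr", "ssim", "rmse", "nrmse", "entropy", "sparse",
        ]
        assert len([l for l in lines if l and l[0].isdigit()]) >= 3 + 9
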