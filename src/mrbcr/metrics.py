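"""Quantitative restoration-quality metrics.

Scalar metrics (all computed in float64 on normalized [0, 1] images):

* PSNR = 10 log10(MAX^2 / MSE), MAX defaulting to 1.0 for normalized data.
* SSIM in its *global-statistics* form: means, variances and covariance over
  the whole image with stabilizers C1 = (0.01 MAX)^2, C2 = (0.03 MAX)^2.
  A windowed variant (the sliding-window convention common in other tools)
  is available behind a flag.
* RMSE and range-normalized NRMSE (divided by max(GT) - min(GT)).
* Shannon entropy of the 8-bit intensity histogram (rounded quantization,
  256 levels), in bits in [0, 8]; low entropy marks sparse images. Image
  sets can be stratified into sparse/dense groups at an entropy threshold
  (default 5 bits, strict < for sparse).

Fourier Ring Correlation (FRC) measures agreement between two images per
radial spatial-frequency shell:

    FRC(r) = Re[ sum_{k in K_r} A(k) conj(B(k)) ]
             / sqrt( sum |A|^2 * sum |B|^2 )

with shells K_r = {k : r - 0.5 <= |k| < r + 0.5} on centered integer
frequency coordinates, r = 0 ... floor(P/2). Curves can be aggregated
across image sets (per-shell mean/std) and compared via the
restoration-to-input difference curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity as _sk_ssim

__all__ = [
    "MetricsConfig",
    "FRCCurve",
    "psnr",
    "ssim",
    "nrmse",
    "entropy",
    "stratify_by_entropy",
    "frc_curve",
    "frc_aggregate",
    "evaluate_pairs",
    "write_report",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Constants shared by the scalar metrics."""

    max_val: float = 1.0
    ssim_c1: float | None = None  # default (0.01 * max_val)**2
    ssim_c2: float | None = None  # default (0.03 * max_val)**2
    entropy_bins: int = 256
    sparsity_threshold: float = 5.0

    def __post_init__(self):
        if self.max_val <= 0:
            raise ValueError("max_val must be > 0")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")

    @property
    def c1(self) -> float:
        return self.ssim_c1 if self.ssim_c1 is not None else (0.01 * self.max_val) ** 2

    @property
    def c2(self) -> float:
        return self.ssim_c2 if self.ssim_c2 is not None else (0.03 * self.max_val) ** 2


@dataclass
class FRCCurve:
    """Per-shell correlation values, optionally aggregated over a set."""

    shell_radii: np.ndarray
    values: np.ndarray
    n_images: int = 1
    std: np.ndarray | None = None
    pixel_size: float | None = None

    def frequencies(self) -> np.ndarray:
        """Shell radii as physical spatial frequencies (1/length units)
        when a pixel size is attached, else cycles per image width."""
        p = 2 * (len(self.shell_radii) - 1)
        if self.pixel_size:
            return self.shell_radii / (p * self.pixel_size)
        return self.shell_radii / p


def _check_pair(pred, gt):
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def psnr(pred: np.ndarray, gt: np.ndarray, cfg: MetricsConfig = MetricsConfig()) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    pred, gt = _check_pair(pred, gt)
    mse = float(np.mean((pred - gt) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(cfg.max_val**2 / mse))


def ssim(
    pred: np.ndarray,
    gt: np.ndarray,
    cfg: MetricsConfig = MetricsConfig(),
    windowed: bool = False,
) -> float:
    """Structural similarity; global-statistics form by default.

    With ``windowed=True`` the conventional sliding-window mean SSIM is
    computed instead (7x7 uniform window, for cross-tool comparison).
    """
    pred, gt = _check_pair(pred, gt)
    if windowed:
        return float(
            _sk_ssim(gt, pred, data_range=cfg.max_val, gaussian_weights=False)
        )
    mu_p, mu_g = pred.mean(), gt.mean()
    var_p, var_g = pred.var(), gt.var()
    cov = ((pred - mu_p) * (gt - mu_g)).mean()
    c1, c2 = cfg.c1, cfg.c2
    return float(
        (2 * mu_g * mu_p + c1)
        * (2 * cov + c2)
        / ((mu_g**2 + mu_p**2 + c1) * (var_g + var_p + c2))
    )


def nrmse(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float]:
    """Root-mean-square error and its range-normalized form.

    Returns (rmse, rmse / (max(GT) - min(GT))); a constant ground truth has
    zero range and raises.
    """
    pred, gt = _check_pair(pred, gt)
    rmse = float(np.sqrt(np.mean((pred - gt) ** 2)))
    rng = float(gt.max() - gt.min())
    if rng == 0.0:
        raise ValueError("NRMSE undefined: ground truth has zero intensity range")
    return rmse, rmse / rng


def entropy(image: np.ndarray, cfg: MetricsConfig = MetricsConfig()) -> float:
    """Shannon entropy (bits) of the rounded 8-bit intensity histogram."""
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        warnings.warn("entropy input outside [0, 1]; clipping", stacklevel=2)
        img = np.clip(img, 0.0, 1.0)
    levels = np.round(img * (cfg.entropy_bins - 1)).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=cfg.entropy_bins)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum())


@dataclass
class StratifiedGroup:
    """Aggregate metrics over one sparsity group."""

    name: str
    count: int
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)


def stratify_by_entropy(
    entropies: np.ndarray,
    metrics: dict[str, np.ndarray],
    cfg: MetricsConfig = MetricsConfig(),
) -> tuple[StratifiedGroup, StratifiedGroup, list[tuple[float, dict[str, float]]]]:
    """Partition per-image metrics into sparse (entropy < threshold) and
    dense (entropy >= threshold) groups.

    Returns (sparse_group, dense_group, per_image) where per_image pairs
    each entropy with its metric values for correlation analysis. An empty
    group carries count 0 and NaN aggregates.
    """
    entropies = np.asarray(entropies, dtype=np.float64)
    for name, vals in metrics.items():
        if len(vals) != len(entropies):
            raise ValueError(f"metric '{name}' is misaligned with entropies")
    sparse_mask = entropies < cfg.sparsity_threshold
    groups = []
    for name, mask in (("sparse", sparse_mask), ("dense", ~sparse_mask)):
        grp = StratifiedGroup(name=name, count=int(mask.sum()))
        for mname, vals in metrics.items():
            vals = np.asarray(vals, dtype=np.float64)[mask]
            finite = vals[np.isfinite(vals)]
            grp.mean[mname] = float(finite.mean()) if finite.size else float("nan")
            grp.std[mname] = float(finite.std()) if finite.size else float("nan")
        groups.append(grp)
    per_image = [
        (float(e), {m: float(v[i]) for m, v in metrics.items()})
        for i, e in enumerate(entropies)
    ]
    return groups[0], groups[1], per_image


# ----------------------------------------------------------------------- FRC


def _shell_index(p: int) -> tuple[np.ndarray, int]:
    """Integer shell id per FFT bin for a p x p image (centered coords)."""
    freq = np.fft.fftfreq(p) * p
    kx, ky = np.meshgrid(freq, freq, indexing="ij")
    radius = np.sqrt(kx**2 + ky**2)
    shells = np.floor(radius + 0.5).astype(np.int64)  # r - 0.5 <= |k| < r + 0.5
    return shells, p // 2


def frc_curve(
    img_a: np.ndarray, img_b: np.ndarray, pixel_size: float | None = None
) -> FRCCurve:
    """Fourier Ring Correlation between two equal square images."""
    a, b = _check_pair(img_a, img_b)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"FRC requires square 2D images, got {a.shape}")
    p = a.shape[0]
    fa, fb = np.fft.fft2(a), np.fft.fft2(b)
    shells, rmax = _shell_index(p)
    n_shells = rmax + 1
    keep = shells <= rmax
    idx = shells[keep]
    cross = np.bincount(idx, weights=np.real(fa * np.conj(fb))[keep], minlength=n_shells)
    pow_a = np.bincount(idx, weights=(np.abs(fa) ** 2)[keep], minlength=n_shells)
    pow_b = np.bincount(idx, weights=(np.abs(fb) ** 2)[keep], minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = cross / np.sqrt(pow_a * pow_b)
    values[counts == 0] = np.nan  # empty shell: undefined, not interpolated
    return FRCCurve(
        shell_radii=np.arange(n_shells),
        values=values,
        n_images=1,
        pixel_size=pixel_size,
    )


def frc_aggregate(
    pred_set: np.ndarray,
    input_set: np.ndarray,
    gt_set: np.ndarray,
    pixel_size: float | None = None,
) -> tuple[FRCCurve, FRCCurve, np.ndarray]:
    """Mean/std FRC of prediction-vs-GT and input-vs-GT over aligned sets,
    plus the per-shell restoration-to-input difference of the means."""
    pred_set, input_set, gt_set = (np.asarray(s, np.float64) for s in (pred_set, input_set, gt_set))
    if not (len(pred_set) == len(input_set) == len(gt_set)):
        raise ValueError("pred/input/GT sets must be aligned in length")
    if len(pred_set) == 0:
        raise ValueError("empty image sets")

    def agg(set_a, set_b):
        curves = np.stack([frc_curve(a, b).values for a, b in zip(set_a, set_b)])
        radii = np.arange(curves.shape[1])
        return FRCCurve(
            shell_radii=radii,
            values=curves.mean(axis=0),
            std=curves.std(axis=0),
            n_images=len(curves),
            pixel_size=pixel_size,
        )

    pred_curve = agg(pred_set, gt_set)
    input_curve = agg(input_set, gt_set)
    diff = pred_curve.values - input_curve.values
    return pred_curve, input_curve, diff


# ------------------------------------------------------------------ reports


def evaluate_pairs(
    pred_set: np.ndarray, gt_set: np.ndarray, cfg: MetricsConfig = MetricsConfig()
) -> dict[str, np.ndarray]:
    """Per-image PSNR/SSIM/RMSE/NRMSE/entropy over aligned image sets.

    Entropy is computed on the ground-truth image (it characterizes scene
    sparsity, not restoration quality).
    """
    rows = {k: [] for k in ("psnr", "ssim", "rmse", "nrmse", "entropy")}
    for pred, gt in zip(pred_set, gt_set):
        rows["psnr"].append(psnr(pred, gt, cfg))
        rows["ssim"].append(ssim(pred, gt, cfg))
        r, nr = nrmse(pred, gt)
        rows["rmse"].append(r)
        rows["nrmse"].append(nr)
        rows["entropy"].append(entropy(gt, cfg))
    return {k: np.asarray(v) for k, v in rows.items()}


def write_report(
    path,
    per_image: dict[str, np.ndarray],
    cfg: MetricsConfig = MetricsConfig(),
    frc_table: FRCCurve | None = None,
) -> None:
    """Write a delimited-text evaluation report (one row per image) and an
    optional shell-wise FRC table appended below."""
    cols = ["psnr", "ssim", "rmse", "nrmse", "entropy"]
    lines = ["id\t" + "\t".join(cols) + "\tsparse"]
    n = len(next(iter(per_image.values())))
    for i in range(n):
        vals = [f"{float(per_image[c][i]):.6g}" for c in cols]
        sparse = per_image["entropy"][i] < cfg.sparsity_threshold
        lines.append(f"{i}\t" + "\t".join(vals) + f"\t{int(sparse)}")
    if frc_table is not None:
        lines.append("")
        lines.append("shell_radius\tfrc_mean\tfrc_std")
        std = frc_table.std if frc_table.std is not None else np.zeros_like(frc_table.values)
        for r, v, s in zip(frc_table.shell_radii, frc_table.values, std):
            lines.append(f"{int(r)}\t{v:.6g}\t{s:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
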