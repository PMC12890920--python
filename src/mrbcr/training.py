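"""Combined spatial + Fourier loss and the optimization loop.

The training objective is a weighted sum of a pixel-space mean-squared
error and a Fourier-magnitude term,

    L_total = w_mse * L_MSE + w_ft * L_FT,      defaults w_mse=1.0, w_ft=0.5

where L_MSE is the mean squared difference between restored and ground-
truth images and L_FT is the mean magnitude of the difference of their 2D
discrete Fourier transforms (orthonormal convention, averaged over
frequency bins and images). The Fourier term penalizes spectral deviations
uniformly across frequencies, complementing the MSE's bias toward
low-frequency fidelity.

Optimization uses Adam with seeded per-epoch shuffling, per-epoch
validation, early stopping on the validation total loss, and best-weights
restoration.
"""

from __future__ import annotations

import copy
import sys
from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from .io import DatasetSplit, TrainConfig
from .model import MRBCR

__all__ = ["LossBreakdown", "TrainHistory", "compute_loss", "train_model"]


@dataclass(frozen=True)
class LossBreakdown:
    """One evaluation of the combined loss and its components."""

    l_mse: float
    l_ft: float
    l_total: float

    @classmethod
    def combine(cls, l_mse: float, l_ft: float, w_mse: float, w_ft: float):
        return cls(l_mse=float(l_mse), l_ft=float(l_ft), l_total=float(w_mse * l_mse + w_ft * l_ft))


@dataclass
class TrainHistory:
    """Per-epoch loss record of one training run."""

    train: list[LossBreakdown] = field(default_factory=list)
    val: list[LossBreakdown] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.train)


def compute_loss(
    pred: np.ndarray, gt: np.ndarray, weights: tuple[float, float] = (1.0, 0.5)
) -> LossBreakdown:
    """Evaluate the combined loss between (B, P, P) prediction and GT arrays.

    l_mse is the mean over images and pixels of the squared difference;
    l_ft is the mean over images and frequency bins of the magnitude of the
    difference of the orthonormal 2D DFTs.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    if not (np.isfinite(pred).all() and np.isfinite(gt).all()):
        raise ValueError("non-finite values in loss inputs")
    l_mse = float(np.mean((pred - gt) ** 2))
    diff_ft = np.fft.fft2(pred - gt, norm="ortho")
    l_ft = float(np.mean(np.abs(diff_ft)))
    return LossBreakdown.combine(l_mse, l_ft, weights[0], weights[1])


def _downsample_gt(gt: np.ndarray, times: int) -> np.ndarray:
    """2x average-pool a (B, P, P) array `times` times (pyramid targets)."""
    for _ in range(times):
        B, H, W = gt.shape
        gt = gt.reshape(B, H // 2, 2, W // 2, 2).mean(axis=(2, 4))
    return gt


def _batch_loss(model: MRBCR, x: np.ndarray, y: np.ndarray, cfg: TrainConfig):
    """Forward pass + autodiff loss tensor and its component values."""
    outputs = model.forward(x)
    scales = range(len(outputs)) if model.spec.multiscale_supervision else (0,)
    total = None
    mse_val = ft_val = 0.0
    for s in scales:
        target = _downsample_gt(y, s)[..., None]
        l_mse = ag.mse_loss(outputs[s], target)
        l_ft = ag.ft_loss(outputs[s], target)
        term = cfg.loss_weight_mse * l_mse + cfg.loss_weight_ft * l_ft
        total = term if total is None else total + term
        if s == 0:
            mse_val, ft_val = float(l_mse.data), float(l_ft.data)
    if len(tuple(scales)) > 1:
        total = total * (1.0 / len(tuple(scales)))
    return total, mse_val, ft_val


def _evaluate(model: MRBCR, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> LossBreakdown:
    """Finest-scale validation loss, computed in minibatches."""
    n = len(x)
    mse_sum = ft_sum = 0.0
    for i in range(0, n, cfg.batch_size):
        xb, yb = x[i : i + cfg.batch_size], y[i : i + cfg.batch_size]
        pred = model.predict(xb)
        part = compute_loss(pred, yb, (cfg.loss_weight_mse, cfg.loss_weight_ft))
        mse_sum += part.l_mse * len(xb)
        ft_sum += part.l_ft * len(xb)
    return LossBreakdown.combine(
        mse_sum / n, ft_sum / n, cfg.loss_weight_mse, cfg.loss_weight_ft
    )


def train_model(
    model: MRBCR,
    data: DatasetSplit,
    cfg: TrainConfig,
    log_file=None,
    max_steps: int | None = None,
) -> tuple[MRBCR, TrainHistory]:
    """Optimize the network on a paired dataset.

    Runs Adam at ``cfg.learning_rate`` with seeded per-epoch shuffling;
    after each epoch the validation total loss is evaluated, and training
    stops at ``cfg.max_epochs`` (or after ``max_steps`` gradient steps, if
    given) or once validation has not improved for
    ``cfg.early_stop_patience`` epochs. The returned model carries the
    best-validation weights.
    """
    if len(data.x_train) == 0 or len(data.x_val) == 0:
        raise ValueError("train and val splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = ag.Adam(model.params, lr=cfg.learning_rate)
    history = TrainHistory(
        metadata={
            "optimizer": "adam",
            "beta1": opt.beta1,
            "beta2": opt.beta2,
            "eps": opt.eps,
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "seed": cfg.seed,
        }
    )
    best_val = np.inf
    best_state = model.state_dict()
    since_best = 0
    steps = 0
    x_tr = np.ascontiguousarray(data.x_train, dtype=np.float32)
    y_tr = np.ascontiguousarray(data.y_train, dtype=np.float32)
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(x_tr))
        mse_sum = ft_sum = 0.0
        n_seen = 0
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            loss, mse_val, ft_val = _batch_loss(model, x_tr[idx], y_tr[idx], cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, step {steps}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            mse_sum += mse_val * len(idx)
            ft_sum += ft_val * len(idx)
            n_seen += len(idx)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        history.train.append(
            LossBreakdown.combine(
                mse_sum / n_seen, ft_sum / n_seen, cfg.loss_weight_mse, cfg.loss_weight_ft
            )
        )
        val = _evaluate(model, data.x_val, data.y_val, cfg)
        history.val.append(val)
        if val.l_total < best_val:
            best_val = val.l_total
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        line = (
            f"epoch {epoch:4d}  train {history.train[-1].l_total:.6f}  "
            f"val {val.l_total:.6f}  lr {cfg.learning_rate:g}"
        )
        print(line, file=sys.stderr)
        if log_file is not None:
            print(line, file=log_file)
        if max_steps is not None and steps >= max_steps:
            break
        if since_best >= cfg.early_stop_patience:
            history.stopped_early = True
            break
    model.load_state_dict(best_state)
    return model, history
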