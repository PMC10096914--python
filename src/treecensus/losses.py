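"""Training losses.

All losses accept either plain numpy arrays (returning a float) or
:class:`treecensus.nn.Tensor` predictions (returning a scalar Tensor
through which gradients flow); reference masks, weights and targets are
always plain arrays.

* ``tversky_loss`` — pixel-weighted Tversky loss for crown segmentation,
  a generalisation of 1 - Dice with separate false-positive (alpha) and
  false-negative (beta) penalties; gap pixels carry a higher weight so
  that filling the corridor between two touching crowns costs more than
  an ordinary false positive.
* ``density_mse`` — pixel-wise MSE for the counting (density) branch.
* ``combined_loss`` — l_seg + lambda_t * l_count with a nondecreasing
  lambda schedule starting at 100.
* ``weighted_mae`` — height-regression MAE where reference heights of
  10 m or more are weighted by 5 to counter underprediction of tall trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autodiff import Tensor

__all__ = [
    "TverskyConfig",
    "LossSchedule",
    "HeightLossConfig",
    "tversky_loss",
    "density_mse",
    "combined_loss",
    "weighted_mae",
]


@dataclass(frozen=True)
class TverskyConfig:
    """False-positive weight alpha, false-negative weight beta."""

    alpha: float = 0.4
    beta: float = 0.6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError("alpha, beta must be >= 0 with alpha + beta > 0")


@dataclass(frozen=True)
class LossSchedule:
    """lambda_t ramp for the combined loss: linear from lambda0 to lambda_final.

    lambda0 defaults to 100; the ceiling (default 10000) is reached at
    total_epochs - 1 and held, keeping the schedule nondecreasing.
    """

    lambda0: float = 100.0
    lambda_final: float = 10000.0
    total_epochs: int = 100

    def __post_init__(self):
        if self.lambda_final < self.lambda0:
            raise ValueError("lambda_final must be >= lambda0")
        if self.total_epochs < 1:
            raise ValueError("total_epochs must be >= 1")

    def value(self, epoch: int) -> float:
        if epoch < 0:
            raise ValueError("epoch must be >= 0")
        if self.total_epochs == 1:
            return self.lambda0
        frac = min(epoch / (self.total_epochs - 1), 1.0)
        return self.lambda0 + frac * (self.lambda_final - self.lambda0)


@dataclass(frozen=True)
class HeightLossConfig:
    """Weight applied to pixels whose reference height is >= threshold (m)."""

    weight: float = 5.0
    threshold_m: float = 10.0

    def __post_init__(self):
        if self.weight < 1:
            raise ValueError("weight must be >= 1")
        if self.threshold_m <= 0:
            raise ValueError("threshold_m must be positive")


def _scalar(x):
    return x.item() if isinstance(x, Tensor) else float(x)


def tversky_loss(p0, g0, w=None, cfg: TverskyConfig = TverskyConfig()):
    """Pixel-weighted Tversky loss.

    1 - sum(w p0 g0) / (sum(w p0 g0) + alpha sum(w p0 g1) + beta sum(w p1 g0))
    with p1 = 1 - p0 and g1 = 1 - g0. With uniform weights and
    alpha = beta = 0.5 this is exactly 1 - Dice. The degenerate
    empty-truth / empty-prediction case is defined as loss 0.
    """
    g0 = np.asarray(g0, dtype=np.float64)
    if w is None:
        w = np.ones_like(g0)
    w = np.asarray(w, dtype=np.float64)
    g1 = 1.0 - g0
    tp = (p0 * (w * g0)).sum()
    fp = (p0 * (w * g1)).sum()
    fn = ((1.0 - p0) * (w * g0)).sum()
    denom = tp + cfg.alpha * fp + cfg.beta * fn
    if _scalar(denom) == 0.0:
        return 0.0
    return 1.0 - tp / denom


def density_mse(d_pred, d_gt):
    """Mean over pixels of squared density differences."""
    d_gt = np.asarray(d_gt, dtype=np.float64)
    pred_shape = d_pred.shape if hasattr(d_pred, "shape") else np.shape(d_pred)
    if tuple(pred_shape) != d_gt.shape:
        raise ValueError(f"shape mismatch: {tuple(pred_shape)} vs {d_gt.shape}")
    return ((d_pred - d_gt) ** 2).mean()


def combined_loss(l_seg, l_count, epoch: int, schedule: LossSchedule = LossSchedule()):
    """Total two-branch loss l_seg + lambda_epoch * l_count."""
    return l_seg + schedule.value(epoch) * l_count


def weighted_mae(y, y_hat, cfg: HeightLossConfig = HeightLossConfig()):
    """Height loss: |y - y_hat|, up-weighted by cfg.weight where y >= threshold."""
    y = np.asarray(y, dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("reference heights must be nonnegative")
    pred_shape = y_hat.shape if hasattr(y_hat, "shape") else np.shape(y_hat)
    if tuple(pred_shape) != y.shape:
        raise ValueError(f"shape mismatch: {tuple(pred_shape)} vs {y.shape}")
    weights = np.where(y >= cfg.threshold_m, cfg.weight, 1.0)
    if isinstance(y_hat, Tensor):
        return ((y_hat - y).abs() * weights).mean()
    return float(np.mean(weights * np.abs(y - y_hat)))
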