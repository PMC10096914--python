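"""Evaluation metrics.

Sign convention for relative bias: mean of (prediction - reference) /
reference, so overprediction is positive and underprediction negative.
Overall bias is the aggregate-level analogue |sum(pred - ref)| / |sum ref|,
which lets per-sample errors cancel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "r2",
    "mae_rmae",
    "relative_bias",
    "overall_bias",
    "mse_decomposition",
    "pixel_prf",
    "object_prf",
    "metrics_table",
]


def _pair(y, y_hat):
    y = np.asarray(y, dtype=np.float64).ravel()
    y_hat = np.asarray(y_hat, dtype=np.float64).ravel()
    if y.shape != y_hat.shape:
        raise ValueError("reference and prediction must have equal length")
    if y.size < 1:
        raise ValueError("empty sample")
    return y, y_hat


def r2(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y, y_hat = _pair(y, y_hat)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R2 undefined: all reference values equal")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot


def mae_rmae(y, y_hat) -> tuple[float, float]:
    """MAE and MAE divided by the mean reference value."""
    y, y_hat = _pair(y, y_hat)
    mae = float(np.abs(y - y_hat).mean())
    ybar = float(y.mean())
    if ybar == 0:
        raise ValueError("rMAE undefined: mean reference is zero")
    return mae, mae / ybar


def relative_bias(y, y_hat) -> float:
    """Mean of (y_hat - y) / y over samples; positive = overprediction."""
    y, y_hat = _pair(y, y_hat)
    if np.any(y == 0):
        raise ValueError("relative bias undefined for zero reference values")
    return float(((y_hat - y) / y).mean())


def overall_bias(y, y_hat) -> float:
    """|sum(y_hat - y)| / |sum y| — bias of the aggregate."""
    y, y_hat = _pair(y, y_hat)
    total = float(y.sum())
    if total == 0:
        raise ValueError("overall bias undefined: reference sum is zero")
    return abs(float((y_hat - y).sum())) / abs(total)


def mse_decomposition(y, y_hat) -> tuple[float, float]:
    """Split MSE into squared bias plus mean squared variation.

    (mean(y) - mean(y_hat))^2 + mean(((y - mean(y)) - (y_hat - mean(y_hat)))^2);
    the two terms are nonnegative and sum exactly to the MSE.
    """
    y, y_hat = _pair(y, y_hat)
    sq_bias = float((y.mean() - y_hat.mean()) ** 2)
    variation = float((((y - y.mean()) - (y_hat - y_hat.mean())) ** 2).mean())
    return sq_bias, variation


def pixel_prf(pred_mask, ref_mask) -> tuple[float, float, float]:
    """Pixel-level precision, recall and F1 (= Dice) on binary masks."""
    pred = np.asarray(pred_mask).astype(bool)
    ref = np.asarray(ref_mask).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError("masks must have the same shape")
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((~pred & ref).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


def object_prf(pred_labels, ref_labels, iou_threshold: float = 0.5) -> tuple[float, float, float]:
    """Object-level PRF via greedy IoU matching of labelled components.

    Optional complement to ``pixel_prf``; not used by the standard
    evaluations, which are pixel-level.
    """
    pred = np.asarray(pred_labels)
    ref = np.asarray(ref_labels)
    pred_ids = [i for i in np.unique(pred) if i != 0]
    ref_ids = [i for i in np.unique(ref) if i != 0]
    matched_ref: set = set()
    tp = 0
    for pid in pred_ids:
        pmask = pred == pid
        best_iou, best_ref = 0.0, None
        for rid in ref_ids:
            if rid in matched_ref:
                continue
            rmask = ref == rid
            inter = int((pmask & rmask).sum())
            if inter == 0:
                continue
            iou = inter / int((pmask | rmask).sum())
            if iou > best_iou:
                best_iou, best_ref = iou, rid
        if best_ref is not None and best_iou >= iou_threshold:
            tp += 1
            matched_ref.add(best_ref)
    precision = tp / len(pred_ids) if pred_ids else 0.0
    recall = tp / len(ref_ids) if ref_ids else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return precision, recall, f1


def metrics_table(df: pd.DataFrame, ref_col: str, pred_col: str,
                  group_by: str | None = None) -> pd.DataFrame:
    """Per-group metrics table (R2, MAE, rMAE, relative and overall bias).

    ``group_by`` may name a column such as forest type or a 5-m height bin.
    """
    def compute(sub: pd.DataFrame) -> pd.Series:
        y, yh = sub[ref_col].to_numpy(), sub[pred_col].to_numpy()
        mae, rmae = mae_rmae(y, yh)
        out = {
            "n": len(sub),
            "mae": mae,
            "rmae": rmae,
            "overall_bias": overall_bias(y, yh),
        }
        out["r2"] = r2(y, yh) if len(np.unique(y)) > 1 else np.nan
        out["relative_bias"] = relative_bias(y, yh) if not np.any(y == 0) else np.nan
        return pd.Series(out)

    if group_by is None:
        return compute(df).to_frame("all").T
    return df.groupby(group_by, observed=True).apply(compute, include_groups=False)
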