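"""Patch sampling, standardisation, augmentation, optimisation and the
post-hoc linear adjustment.

Training draws random fixed-size patches from the available scenes each
epoch, standardises them (per instance and per channel for the
counting/segmentation model; globally with frozen training-set statistics
for the height model), applies augmentation, and minimises the combined
or height loss with Adam. Model selection keeps the weights from the
epoch with the lowest loss on a fixed set of validation patches.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian as _gaussian_blur

from . import nn
from .containers import BASE_BANDS
from .nn.autodiff import Tensor
from .losses import (TverskyConfig, LossSchedule, HeightLossConfig,
                     tversky_loss, density_mse, combined_loss, weighted_mae)
from .targets import (DensityConfig, make_density_map, make_gap_map,
                      make_weight_map, rasterize_crowns)

__all__ = [
    "TrainConfig",
    "LinearAdjustment",
    "build_count_seg_sample",
    "build_height_sample",
    "extract_patches",
    "standardize_per_instance",
    "compute_global_stats",
    "standardize_global",
    "augment",
    "stratified_split",
    "train_model",
    "make_count_seg_loss",
    "make_height_loss",
    "fit_linear_adjustment",
    "apply_adjustment",
    "mix_datasets",
    "upsample_bilinear",
]


@dataclass(frozen=True)
class TrainConfig:
    patch_size: int = 256
    batch_size: int = 8
    epochs: int = 100
    learning_rate: float = 1e-4
    final_learning_rate: float | None = None  # linear decay target, None = constant
    patches_per_epoch: int = 40
    val_patches: int = 800
    val_patch_size: int | None = None  # None: same as patch_size
    seed: int = 0
    standardization: str = "per_instance"  # or "global"
    val_fraction: float = 0.2              # 4:1 split
    augment: bool = True

    def __post_init__(self):
        if self.patch_size < 8 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid training configuration")
        if self.standardization not in ("per_instance", "global"):
            raise ValueError("standardization must be 'per_instance' or 'global'")


@dataclass(frozen=True)
class LinearAdjustment:
    """Fit prediction = a * reference + b; invert as (prediction - b) / a."""

    a: float
    b: float

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("slope a must be nonzero")


# ---------------------------------------------------------------------------
# training samples from scenes

def build_count_seg_sample(raster, annotations, gap_radius_px: int = 3,
                           gap_weight: float = 5.0,
                           density_cfg: DensityConfig = DensityConfig(),
                           density_scale: float = 1.0) -> dict:
    """Image plus the three training targets for the dual-branch model.

    ``density_scale`` multiplies the density target (pass the model's
    ModelConfig.density_scale): training against a scaled target brings
    the counting branch's output range close to the segmentation
    probabilities, which a zero-initialised head reaches much more
    reliably; predictions are divided back to trees/pixel at inference.
    """
    shape = raster.base_shape
    return {
        "image": raster.stack(BASE_BANDS),
        "mask": rasterize_crowns(annotations, shape),
        "weights": make_weight_map(make_gap_map(annotations, shape, gap_radius_px),
                                   gap_weight),
        "density": density_scale * make_density_map(annotations, shape, density_cfg),
    }


def build_height_sample(raster, height_band: str = "height") -> dict:
    """Image plus the half-resolution height target for the height model."""
    return {"image": raster.stack(BASE_BANDS),
            "height": np.asarray(raster.bands[height_band], dtype=np.float64)}


# ---------------------------------------------------------------------------
# patches

def extract_patches(sample: dict, patch_size: int, n: int, rng: np.random.Generator):
    """Yield n aligned random patches from one training sample.

    ``sample`` maps names to grids: 'image' is (C, H, W); any other key is
    either a full-resolution (H, W) grid or a half-resolution grid
    (H/2, W/2), e.g. 'coarse' inputs or height targets. Offsets are drawn
    uniformly over even positions so half-resolution grids crop to
    exactly co-located windows.
    """
    img = sample["image"]
    _, h, w = img.shape
    p = patch_size
    if h < p or w < p:
        raise ValueError(f"scene ({h}x{w}) smaller than patch size {p}")
    for _ in range(n):
        r0 = 2 * int(rng.integers(0, (h - p) // 2 + 1))
        c0 = 2 * int(rng.integers(0, (w - p) // 2 + 1))
        patch = {}
        for key, grid in sample.items():
            if key == "image":
                patch[key] = grid[:, r0:r0 + p, c0:c0 + p]
            elif grid.ndim == 2 and grid.shape == (h, w):
                patch[key] = grid[r0:r0 + p, c0:c0 + p]
            elif grid.ndim == 2 and grid.shape == (h // 2, w // 2):
                patch[key] = grid[r0 // 2:(r0 + p) // 2, c0 // 2:(c0 + p) // 2]
            elif grid.ndim == 3 and grid.shape[1:] == (h // 2, w // 2):
                patch[key] = grid[:, r0 // 2:(r0 + p) // 2, c0 // 2:(c0 + p) // 2]
            else:
                raise ValueError(f"grid {key!r} has unexpected shape {grid.shape}")
        yield patch


# ---------------------------------------------------------------------------
# standardisation

def standardize_per_instance(image: np.ndarray) -> np.ndarray:
    """Zero-mean unit-SD per channel; constant channels map to zeros."""
    out = np.empty_like(image, dtype=np.float64)
    for c in range(image.shape[0]):
        band = image[c]
        sd = band.std()
        out[c] = 0.0 if sd == 0 else (band - band.mean()) / sd
    return out


def compute_global_stats(images: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean and SD pooled over the training images only."""
    stacked = np.concatenate([img.reshape(img.shape[0], -1) for img in images], axis=1)
    return stacked.mean(axis=1), stacked.std(axis=1)


def standardize_global(image: np.ndarray, stats: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, sd = stats
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"band {bad} has zero SD in the training statistics")
    return (image - mean[:, None, None]) / sd[:, None, None]


# ---------------------------------------------------------------------------
# augmentation

def augment(patch: dict, rng: np.random.Generator) -> dict:
    """Random flips (all grids), blur and brightness (image only).

    Geometric transforms are applied identically to the image and every
    target so alignment and the density integral are preserved;
    photometric transforms never touch the targets. Random cropping is
    realised upstream by the random patch extraction itself.
    """
    out = dict(patch)
    if rng.random() < 0.5:  # horizontal flip
        out = {k: (v[..., ::-1]).copy() for k, v in out.items()}
    if rng.random() < 0.5:  # vertical flip
        out = {k: (v[..., ::-1, :]).copy() for k, v in out.items()}
    img = out["image"].astype(np.float64)
    if rng.random() < 0.5:  # Gaussian blur
        sigma = rng.uniform(0.3, 1.2)
        img = np.stack([_gaussian_blur(b, sigma=sigma, preserve_range=True) for b in img])
    if rng.random() < 0.5:  # brightness
        img = img * rng.uniform(0.85, 1.15) + rng.uniform(-8.0, 8.0)
    out["image"] = img
    return out


# ---------------------------------------------------------------------------
# splitting / dataset mixing

def stratified_split(samples: list, strata: list, val_fraction: float = 0.2,
                     rng: np.random.Generator | None = None):
    """Split preserving per-stratum proportions to within one sample."""
    if len(samples) != len(strata):
        raise ValueError("samples and strata must have equal length")
    rng = rng or np.random.default_rng(0)
    train_idx, val_idx = [], []
    for s in sorted(set(strata)):
        idx = [i for i, lab in enumerate(strata) if lab == s]
        idx = list(rng.permutation(idx))
        n_val = int(round(val_fraction * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return [samples[i] for i in sorted(train_idx)], [samples[i] for i in sorted(val_idx)]


def mix_datasets(primary: list, extra: list, oversample_extra: int = 5) -> list:
    """Fine-tuning mix: the extra dataset is repeated oversample_extra times."""
    if oversample_extra < 1:
        raise ValueError("oversample_extra must be >= 1")
    return list(primary) + list(extra) * oversample_extra


def upsample_bilinear(grid: np.ndarray, factor: int = 2) -> np.ndarray:
    """Bilinear up-sampling for adapting coarser imagery before fine-tuning."""
    zoom = [1.0] * (grid.ndim - 2) + [factor, factor]
    return ndimage.zoom(grid, zoom, order=1, grid_mode=True, mode="nearest")


# ---------------------------------------------------------------------------
# losses as training closures

def make_count_seg_loss(tversky_cfg: TverskyConfig = TverskyConfig(),
                        schedule: LossSchedule = LossSchedule()):
    """Closure computing l_seg + lambda_t * l_count for one batch."""

    def loss_fn(outputs: dict, batch: dict, epoch: int):
        l_seg = tversky_loss(outputs["seg"], batch["mask"], batch["weights"], tversky_cfg)
        l_count = density_mse(outputs["density"], batch["density"])
        lam = schedule.value(epoch)
        total = combined_loss(l_seg, l_count, epoch, schedule)
        logs = {"l_seg": float(l_seg.item() if isinstance(l_seg, Tensor) else l_seg),
                "l_count": float(l_count.item() if isinstance(l_count, Tensor) else l_count),
                "lambda_t": lam}
        return total, logs

    return loss_fn


def make_count_seg_val_loss(tversky_cfg: TverskyConfig = TverskyConfig(),
                            schedule: LossSchedule = LossSchedule(),
                            density_scale: float = 1.0,
                            count_weight: float = 0.1):
    """Validation criterion for model selection: the combined loss plus a
    per-patch count-integral error term.

    The pixel-wise density MSE is dominated by kernel shape and is nearly
    blind to a small systematic miscalibration of the map's integral —
    which is exactly the quantity counting cares about. Adding the mean
    squared count error (in trees, via density_scale) makes the validation
    minimum land on calibrated epochs. Use together with full-scene
    validation patches (TrainConfig.val_patch_size) so patch borders do
    not clip kernel mass.
    """
    base_fn = make_count_seg_loss(tversky_cfg, schedule)

    def loss_fn(outputs: dict, batch: dict, epoch: int):
        total, logs = base_fn(outputs, batch, epoch)
        pred = outputs["density"]
        pred = pred.data if isinstance(pred, Tensor) else np.asarray(pred)
        count_err = ((pred.sum(axis=(1, 2)) - batch["density"].sum(axis=(1, 2)))
                     / density_scale) ** 2
        err = float(count_err.mean())
        logs["val_count_sq_error"] = err
        return total + count_weight * err, logs

    return loss_fn


def make_height_loss(cfg: HeightLossConfig = HeightLossConfig()):
    def loss_fn(outputs: dict, batch: dict, epoch: int):
        l = weighted_mae(batch["height"], outputs["height"], cfg)
        return l, {"l_height": float(l.item() if isinstance(l, Tensor) else l)}

    return loss_fn


# ---------------------------------------------------------------------------
# the training loop

def _standardize_batch(images: list[np.ndarray], cfg: TrainConfig, stats):
    if cfg.standardization == "per_instance":
        return [standardize_per_instance(im) for im in images]
    return [standardize_global(im, stats) for im in images]


def _make_batches(patches: list[dict], cfg: TrainConfig, stats):
    """Group patches into (inputs, coarse, targets) batches."""
    batches = []
    bs = cfg.batch_size
    for i in range(0, len(patches), bs):
        group = patches[i:i + bs]
        if not group:
            continue
        imgs = _standardize_batch([p["image"] for p in group], cfg, stats)
        batch = {"image": np.stack(imgs).astype(np.float32)}
        if "coarse" in group[0]:
            batch["coarse"] = np.stack([p["coarse"] for p in group]).astype(np.float32)
        for key in group[0]:
            if key not in ("image", "coarse"):
                batch[key] = np.stack([p[key] for p in group])
        batches.append(batch)
    return batches


def _forward(model, batch, training: bool):
    coarse = Tensor(batch["coarse"]) if "coarse" in batch else None
    outputs = model(Tensor(batch["image"]), coarse)
    # heads emit (N,1,H,W); losses compare against (N,H,W) targets
    return {k: _squeeze1(v) for k, v in outputs.items()}


def _squeeze1(t: Tensor) -> Tensor:
    data = t.data[:, 0]
    out = Tensor(data, parents=(t,))

    def backward(g, t=t):
        if t.requires_grad:
            t.accumulate(g[:, None])

    out._backward = backward if out.requires_grad else None
    return out


def train_model(model, train_samples: list[dict], val_samples: list[dict],
                loss_fn, cfg: TrainConfig, global_stats=None, val_loss_fn=None):
    """Train, selecting the weights with the lowest validation loss.

    Samples are dicts of aligned grids (see :func:`extract_patches`).
    Returns (best_state_dict, history DataFrame); the model is left loaded
    with the best weights. The per-epoch history carries the CSV log
    columns epoch, l_seg/l_count (when present), lambda_t, combined and
    val_loss. ``val_loss_fn`` optionally replaces ``loss_fn`` as the
    validation criterion (e.g. :func:`make_count_seg_val_loss`).
    """
    if not train_samples or not val_samples:
        raise ValueError("training and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    stats = global_stats
    if cfg.standardization == "global" and stats is None:
        stats = compute_global_stats([s["image"] for s in train_samples])

    # fixed validation patches, chosen once before training
    val_patches = []
    vrng = np.random.default_rng(cfg.seed + 1)
    val_size = cfg.val_patch_size or cfg.patch_size
    per_scene = max(1, cfg.val_patches // len(val_samples))
    for sample in val_samples:
        val_patches.extend(extract_patches(sample, val_size, per_scene, vrng))
    val_patches = val_patches[: cfg.val_patches]
    val_batches = _make_batches(val_patches, cfg, stats)
    if val_loss_fn is None:
        val_loss_fn = loss_fn

    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    history = []
    best_val = np.inf
    best_state = None
    for epoch in range(cfg.epochs):
        if cfg.final_learning_rate is not None and cfg.epochs > 1:
            frac = epoch / (cfg.epochs - 1)
            opt.lr = cfg.learning_rate + frac * (cfg.final_learning_rate
                                                 - cfg.learning_rate)
        model.train()
        epoch_logs: dict[str, float] = {}
        train_loss = 0.0
        n_steps = 0
        patches = []
        for _ in range(cfg.patches_per_epoch):
            sample = train_samples[rng.integers(len(train_samples))]
            patch = next(extract_patches(sample, cfg.patch_size, 1, rng))
            if cfg.augment:
                patch = augment(patch, rng)
            patches.append(patch)
        for batch in _make_batches(patches, cfg, stats):
            outputs = _forward(model, batch, training=True)
            loss, logs = loss_fn(outputs, batch, epoch)
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_loss += loss.item()
            for k, v in logs.items():
                epoch_logs[k] = epoch_logs.get(k, 0.0) + v
            n_steps += 1
        train_loss /= n_steps
        epoch_logs = {k: v / n_steps if k != "lambda_t" else v / n_steps
                      for k, v in epoch_logs.items()}

        model.eval()
        val_loss = 0.0
        with nn.no_grad():
            for batch in val_batches:
                outputs = _forward(model, batch, training=False)
                # evaluate at the final epoch's loss weighting so validation
                # losses are comparable across epochs despite the lambda ramp
                loss, _ = val_loss_fn(outputs, batch, cfg.epochs - 1)
                val_loss += loss.item() if isinstance(loss, Tensor) else float(loss)
        val_loss /= len(val_batches)

        if val_loss < best_val:
            best_val = val_loss
            best_state = copy.deepcopy(model.state_dict())
        history.append({"epoch": epoch, "combined": train_loss,
                        "val_loss": val_loss, **epoch_logs})

    model.load_state_dict(best_state)
    return best_state, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# post-hoc linear adjustment

def fit_linear_adjustment(predictions, references) -> LinearAdjustment:
    """OLS of prediction (response) on reference (covariate): pred = a*ref + b."""
    pred = np.asarray(predictions, dtype=np.float64).ravel()
    ref = np.asarray(references, dtype=np.float64).ravel()
    if pred.shape != ref.shape:
        raise ValueError("predictions and references must have equal length")
    if np.unique(ref).size < 2:
        raise ValueError("need at least 2 distinct reference values")
    a, b = np.polyfit(ref, pred, 1)
    return LinearAdjustment(a=float(a), b=float(b))


def apply_adjustment(y, adj: LinearAdjustment):
    """Invert the fitted distortion: adjusted = (y - b) / a."""
    return (np.asarray(y, dtype=np.float64) - adj.b) / adj.a
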