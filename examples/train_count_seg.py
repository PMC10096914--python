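"""Train a small dual-branch counting/segmentation U-Net on synthetic scenes.

A deliberately small run (8 scenes, 25 epochs, 64-px patches) to show the
workflow: build targets, train with the gap-weighted Tversky loss plus the
lambda-weighted density MSE, then count held-out trees by integrating the
predicted density map. Expect a few minutes on one CPU; accuracy improves
with the longer schedule used in scripts/acceptance.py.
"""

import numpy as np

from treecensus.containers import BASE_BANDS
from treecensus.infer import count_from_density, predict_tiles
from treecensus.losses import LossSchedule, TverskyConfig
from treecensus.model import ModelConfig, build_count_seg_model
from treecensus.synth import SceneConfig, generate_scene, scene_to_annotations
from treecensus.train import (TrainConfig, build_count_seg_sample,
                              make_count_seg_loss, make_count_seg_val_loss,
                              train_model)

regimes = ["deciduous", "coniferous", "nonforest"]

def scene(i):
    rng = np.random.default_rng(100 + i)
    cfg = SceneConfig(width_px=128, height_px=128, regime=regimes[i % 3],
                      n_trees=int(rng.integers(6, 20)),
                      crown_radius_range_m=(0.8, 2.0), seed=100 + i)
    return generate_scene(cfg)

scenes = [scene(i) for i in range(9)]
samples = [build_count_seg_sample(r, scene_to_annotations(t), density_scale=64.0)
           for r, t in scenes[:8]]

model = build_count_seg_model(ModelConfig(in_bands=4, base_channels=8, depth=3,
                                          density_scale=64.0, seed=0))
cfg = TrainConfig(patch_size=64, batch_size=8, epochs=25, learning_rate=3e-3,
                  final_learning_rate=3e-4, patches_per_epoch=40,
                  val_patches=2, val_patch_size=128, seed=0)
sched = LossSchedule(lambda0=1.0, lambda_final=25.0, total_epochs=25)
loss_fn = make_count_seg_loss(TverskyConfig(alpha=0.4, beta=0.6), sched)
val_fn = make_count_seg_val_loss(TverskyConfig(alpha=0.4, beta=0.6), sched,
                                 density_scale=64.0)
_, history = train_model(model, samples[2:], samples[:2], loss_fn, cfg,
                         val_loss_fn=val_fn)
print(history[["epoch", "l_seg", "l_count", "lambda_t", "val_loss"]]
      .iloc[[0, 9, 19, 24]].to_string(index=False))

raster, truth = scenes[8]
out = predict_tiles(model, raster, BASE_BANDS, window=128, overlap=16)
print(f"held-out scene: true count {truth.count}, "
      f"density count {count_from_density(out['density']):.2f}")
print("l_seg is the gap-weighted Tversky loss (0 = perfect overlap); "
      "l_count the density MSE; lambda_t ramps so both matter")
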