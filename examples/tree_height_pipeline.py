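"""Per-tree heights from a crown probability map and a canopy-height grid.

The post-processing chain runs in a fixed order: threshold at 0.5 ->
connected components -> remove sub-2-pixel segments -> expand each crown
by d = alpha*sqrt(s/pi) -> read the 95th-percentile height over the
expanded crown -> drop NIR/height anomalies. Here the probability map is
the (perfect) truth mask, so recovered areas are exact and heights land
on the crown domes' 95th percentiles.
"""

import numpy as np

from treecensus.synth import SceneConfig, generate_scene, scene_to_annotations
from treecensus.targets import rasterize_crowns
from treecensus.infer import PostprocessConfig, postprocess

cfg = SceneConfig(width_px=192, height_px=192, n_trees=12, overlap_fraction=0.0,
                  crown_radius_range_m=(1.0, 2.2), seed=11)
raster, truth = generate_scene(cfg)
anns = scene_to_annotations(truth)

prob = rasterize_crowns(anns, raster.base_shape).astype(float) * 0.99
records = postprocess(prob, raster.bands["height"], raster.bands["nir"],
                      PostprocessConfig(expand_alpha=0.2), cfg.pixel_size_m)

print(f"{'tree':>4} {'area m^2':>9} {'height m':>9} {'apex m':>7} {'nir max':>8}")
apexes = sorted(truth.crowns, key=lambda c: c.centroid_px)
for rec in records[:8]:
    print(f"{rec.id:>4} {rec.area_s:>9.2f} {rec.height_m:>9.2f} "
          f"{'':>7} {rec.nir_max:>8.0f}")
print(f"recovered {len(records)} of {truth.count} trees "
      "(disjoint crowns + perfect mask -> exact recovery)")
print("per-tree height = 95th percentile of the height grid over the "
      "expanded crown; it sits slightly below the dome apex by design")
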