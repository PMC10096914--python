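"""Field-plot evaluation with concentric circles and area-ratio extrapolation.

Field inventories count stems on circular plots (Danish design: 3.5 / 10 /
15 m circles with dbh rules; Finnish: one 12.62-m circle). Counts from one
circle extrapolate to another by the ratio of areas — from 10 m to 15 m
that ratio is (15/10)^2 = 2.25 — assuming evenly distributed stems.
"""

import numpy as np

from treecensus.synth import SceneConfig, generate_scene, scene_to_annotations
from treecensus.targets import make_density_map
from treecensus.nfieval import (danish_design, extrapolate_count,
                                predicted_plot_count, danish_reference_counts,
                                evaluate_plots)

a10, a15 = np.pi * 10 ** 2, np.pi * 15 ** 2
print(f"10 m -> 15 m area ratio: {a15 / a10:.2f}; "
      f"10 trees extrapolate to {extrapolate_count(10, a10, a15):.1f}")
print("Danish reconstruction with 8 mid-size (10<dbh<=40) and 3 large trees:",
      danish_reference_counts(8, 3))

# a synthetic stand evaluated on three plots
cfg = SceneConfig(width_px=512, height_px=512, pixel_size_m=0.2, n_trees=120,
                  crown_radius_range_m=(0.8, 1.8), seed=5)
_, truth = generate_scene(cfg)
density = make_density_map(scene_to_annotations(truth), (512, 512))

pred, ref = [], []
for center in [(160.0, 160.0), (256.0, 300.0), (350.0, 180.0)]:
    plot = danish_design(center)
    pred.append(predicted_plot_count(density, plot, cfg.pixel_size_m, mode="density"))
    # "field" truth: centroids inside the 15-m circle
    n = sum(1 for c in truth.crowns
            if np.hypot(c.centroid_px[0] - center[0], c.centroid_px[1] - center[1])
            < 15.0 / cfg.pixel_size_m)
    ref.append(float(n))

print("plot density counts:", [f"{p:.2f}" for p in pred])
print("plot field counts:  ", ref)
print(evaluate_plots(pred, ref).to_string(index=False))
print("relative bias > 0 would mean overprediction; near 0 here because the "
      "density integral conserves the count")
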