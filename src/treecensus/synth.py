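"""Synthetic aerial-like scenes with exact ground truth.

Scenes emulate 20-cm-class four-band (R, G, B, NIR) orthoimagery over
three landscape regimes — clustered deciduous forest, grid-like
coniferous forest, and sparse nonforest rows (hedgerow-style) — plus a
canopy-height band at twice-coarser resolution, the way LiDAR height
maps typically accompany such imagery.

Each tree is an ellipse-shaped crown with a hemi-ellipsoidal ("dome")
height profile, gradient shading, a cast shadow, and NIR reflectance
well separated from the background (crowns above 80, background below
80, so the NIR/height anomaly filter downstream is exercisable). The
generator returns both the rendered raster stack and a SceneTruth with
crown polygons, centroids, areas, apex heights and the full-resolution
height surface, so every downstream stage can be tested against exact
truth.

Randomness is split into independent streams for placement, texture and
noise: changing the noise level never moves a tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely.affinity
from shapely.geometry import Point, Polygon

from .containers import Annotation, AnnotationSet, RasterStack, centroid_pixel
from .targets import _polygon_mask

__all__ = ["SceneConfig", "CrownTruth", "SceneTruth", "generate_scene", "scene_to_annotations"]

REGIMES = ("deciduous", "coniferous", "nonforest")

# margin (px) keeping crown centroids clear of the border so that the
# 15x15 density kernel never loses mass off-image
_KERNEL_MARGIN = 8

# clearance (px) between crowns placed without overlap; > sqrt(2) keeps
# their pixel masks 8-disconnected
_MIN_GAP_PX = 2.0


@dataclass(frozen=True)
class SceneConfig:
    width_px: int = 256
    height_px: int = 256
    pixel_size_m: float = 0.2
    regime: str = "deciduous"
    n_trees: int = 20
    crown_radius_range_m: tuple[float, float] = (1.0, 3.0)
    height_range_m: tuple[float, float] = (4.0, 25.0)
    overlap_fraction: float = 0.3
    shadow_offset_px: tuple[int, int] = (3, 3)
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("scene dimensions must be positive")
        if self.width_px % 2 or self.height_px % 2:
            raise ValueError("scene dimensions must be even (height band is 2x coarser)")
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        for lo, hi in (self.crown_radius_range_m, self.height_range_m):
            if lo > hi or lo <= 0:
                raise ValueError("ranges must satisfy 0 < min <= max")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CrownTruth:
    polygon: Polygon
    centroid_px: tuple[int, int]
    crown_area_m2: float
    apex_height_m: float


@dataclass
class SceneTruth:
    crowns: list[CrownTruth]
    height_surface: np.ndarray
    pixel_size_m: float = 0.2

    @property
    def count(self) -> int:
        return len(self.crowns)


def _candidate_positions(cfg: SceneConfig, rng: np.random.Generator, margin: float):
    """Infinite stream of candidate crown centres for the regime pattern."""
    w, h = cfg.width_px, cfg.height_px
    lo_x, hi_x = margin, w - margin
    lo_y, hi_y = margin, h - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("scene too small for the requested crown sizes")

    if cfg.regime == "deciduous":
        # parent-offspring clustering: clumped canopies
        n_parents = max(1, cfg.n_trees // 5)
        parents = np.column_stack([
            rng.uniform(lo_x, hi_x, n_parents),
            rng.uniform(lo_y, hi_y, n_parents),
        ])
        spread = 0.35 * min(hi_x - lo_x, hi_y - lo_y)
        while True:
            p = parents[rng.integers(n_parents)]
            xy = p + rng.normal(0.0, spread, 2)
            yield float(np.clip(xy[0], lo_x, hi_x)), float(np.clip(xy[1], lo_y, hi_y))
    elif cfg.regime == "coniferous":
        # jittered planting grid
        k = max(1, int(np.ceil(np.sqrt(max(cfg.n_trees, 1)))))
        xs = np.linspace(lo_x, hi_x, k)
        ys = np.linspace(lo_y, hi_y, k)
        cells = [(x, y) for y in ys for x in xs]
        order = rng.permutation(len(cells))
        jitter = 0.15 * (xs[1] - xs[0] if k > 1 else hi_x - lo_x)
        i = 0
        while True:
            x, y = cells[order[i % len(cells)]]
            i += 1
            yield (float(np.clip(x + rng.normal(0, jitter), lo_x, hi_x)),
                   float(np.clip(y + rng.normal(0, jitter), lo_y, hi_y)))
    else:
        # nonforest: trees along a few sparse rows (hedgerows)
        n_rows = int(rng.integers(1, 4))
        rows_y = rng.uniform(lo_y, hi_y, n_rows)
        while True:
            y0 = rows_y[rng.integers(n_rows)]
            yield (float(rng.uniform(lo_x, hi_x)),
                   float(np.clip(y0 + rng.normal(0, 3.0), lo_y, hi_y)))


def _ellipse(cx: float, cy: float, a: float, b: float, angle_deg: float) -> Polygon:
    circle = Point(cx, cy).buffer(1.0, quad_segs=16)
    ell = shapely.affinity.scale(circle, a, b, origin=(cx, cy))
    return shapely.affinity.rotate(ell, angle_deg, origin=(cx, cy))


def _place_crowns(cfg: SceneConfig, rng: np.random.Generator):
    """Place n_trees elliptical crowns respecting the overlap rule."""
    r_lo = cfg.crown_radius_range_m[0] / cfg.pixel_size_m
    r_hi = cfg.crown_radius_range_m[1] / cfg.pixel_size_m
    margin = r_hi + _KERNEL_MARGIN
    placed: list[dict] = []
    if cfg.n_trees == 0:
        return placed
    stream = _candidate_positions(cfg, rng, margin)
    attempts = 0
    max_attempts = 2000 * cfg.n_trees + 2000
    while len(placed) < cfg.n_trees:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_trees} crowns (placed {len(placed)}); "
                "scene too small or overlap_fraction too low"
            )
        cx, cy = next(stream)
        a = rng.uniform(r_lo, r_hi)
        ratio = rng.uniform(0.7, 1.0)
        b = a * ratio
        angle = rng.uniform(0.0, 180.0)
        poly = _ellipse(cx, cy, a, b, angle)
        allow_overlap = cfg.overlap_fraction > 0 and rng.random() < cfg.overlap_fraction
        ok = True
        for other in placed:
            if allow_overlap:
                # still forbid near-coincident stems
                d = np.hypot(cx - other["cx"], cy - other["cy"])
                if d < 0.5 * (a + other["a"]):
                    ok = False
                    break
            elif poly.distance(other["polygon"]) <= _MIN_GAP_PX:
                # disjoint placement keeps a small clearance so rasterised
                # crowns stay 8-disconnected (no merged components)
                ok = False
                break
        if not ok:
            continue
        apex = rng.uniform(*cfg.height_range_m)
        placed.append(dict(polygon=poly, cx=cx, cy=cy, a=a, b=b,
                           angle=angle, apex=apex))
    return placed


def _dome_values(crown: dict, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Hemi-ellipsoid height profile at the given pixel centres, in [0, 1]."""
    x = cols + 0.5 - crown["cx"]
    y = rows + 0.5 - crown["cy"]
    t = np.deg2rad(crown["angle"])
    u = (x * np.cos(t) + y * np.sin(t)) / crown["a"]
    v = (-x * np.sin(t) + y * np.cos(t)) / crown["b"]
    q = u * u + v * v
    return np.sqrt(np.clip(1.0 - q, 0.0, None))


def generate_scene(config: SceneConfig) -> tuple[RasterStack, SceneTruth]:
    """Render one synthetic scene; bit-identical for a fixed seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_texture, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))

    h, w = config.height_px, config.width_px
    shape = (h, w)
    crowns = _place_crowns(config, rng_place)

    height_surface = np.zeros(shape, dtype=np.float64)
    crown_union = np.zeros(shape, dtype=bool)
    masks = []
    shade = np.zeros(shape, dtype=np.float64)
    for crown in crowns:
        mask = _polygon_mask(crown["polygon"], shape)
        masks.append(mask)
        crown_union |= mask
        rr, cc = np.nonzero(mask)
        z = _dome_values(crown, rr, cc)
        vals = crown["apex"] * z
        np.maximum.at(height_surface, (rr, cc), vals)
        # simple directional shading: bright toward the dome top and the
        # sun-facing (north-west) flank
        x = (cc + 0.5 - crown["cx"]) / crown["a"]
        y = (rr + 0.5 - crown["cy"]) / crown["b"]
        s = 0.55 + 0.45 * z - 0.18 * (x + y) / np.sqrt(2.0)
        np.maximum.at(shade, (rr, cc), np.clip(s, 0.25, 1.1))

    # background texture
    base = {
        "red": rng_texture.normal(95.0, 10.0, shape),
        "green": rng_texture.normal(110.0, 10.0, shape),
        "blue": rng_texture.normal(85.0, 10.0, shape),
        "nir": rng_texture.normal(50.0, 8.0, shape),
    }

    # crown colours per regime
    dark = config.regime == "coniferous"
    crown_rgb = (45.0, 80.0, 40.0) if dark else (60.0, 120.0, 55.0)
    for name, tone in zip(("red", "green", "blue"), crown_rgb):
        band = base[name]
        band[crown_union] = tone * shade[crown_union]
    zsurf = np.zeros(shape)
    if crowns:
        apex_max = max(c["apex"] for c in crowns)
        zsurf = height_surface / apex_max if apex_max > 0 else zsurf
    base["nir"][crown_union] = 150.0 + 70.0 * zsurf[crown_union] * shade[crown_union]

    # cast shadow: crown union shifted by the sun-offset, darkening background
    dy, dx = config.shadow_offset_px
    if crown_union.any() and (dy or dx):
        shadow = np.zeros(shape, dtype=bool)
        src = crown_union[
            max(0, -dy): h - max(0, dy) or h,
            max(0, -dx): w - max(0, dx) or w,
        ]
        shadow[max(0, dy): h - max(0, -dy) or h,
               max(0, dx): w - max(0, -dx) or w] = src
        shadow &= ~crown_union
        for name, factor in (("red", 0.45), ("green", 0.45), ("blue", 0.5), ("nir", 0.7)):
            base[name][shadow] *= factor

    # sensor noise, then clip; NIR is clipped on either side of the 80
    # threshold so crown/background stay separable for the anomaly filter
    for name in base:
        if config.noise_sd > 0:
            base[name] = base[name] + rng_noise.normal(0.0, config.noise_sd, shape)
        base[name] = np.clip(base[name], 0.0, 255.0)
    base["nir"] = np.where(
        crown_union,
        np.clip(base["nir"], 81.0, 255.0),
        np.clip(base["nir"], 0.0, 79.0),
    )

    # coarse canopy-height band: 2x2 block averages of the height surface
    height_band = height_surface.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))

    raster = RasterStack(
        bands={**base, "height": height_band},
        resolution_factor={"red": 1, "green": 1, "blue": 1, "nir": 1, "height": 2},
        pixel_size_m=config.pixel_size_m,
    )

    truths = []
    for crown, mask in zip(crowns, masks):
        apex = float(height_surface[mask].max()) if mask.any() else 0.0
        truths.append(CrownTruth(
            polygon=crown["polygon"],
            centroid_px=centroid_pixel(crown["polygon"]),
            crown_area_m2=crown["polygon"].area * config.pixel_size_m ** 2,
            apex_height_m=apex,
        ))
    truth = SceneTruth(crowns=truths, height_surface=height_surface,
                       pixel_size_m=config.pixel_size_m)
    return raster, truth


def scene_to_annotations(truth: SceneTruth) -> AnnotationSet:
    """Convert scene truth to crown annotations (centroid = nearest pixel)."""
    anns = [
        Annotation(
            polygon=c.polygon,
            centroid_px=centroid_pixel(c.polygon),
            area_m2=c.polygon.area * truth.pixel_size_m ** 2,
            apex_height_m=c.apex_height_m,
        )
        for c in truth.crowns
    ]
    return AnnotationSet(annotations=anns, pixel_size_m=truth.pixel_size_m)
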