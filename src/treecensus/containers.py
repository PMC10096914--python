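"""Core in-memory containers shared across the pipeline.

Conventions: rasters are 2-D numpy arrays indexed (row, col) with the
origin at the top-left pixel; polygon coordinates are in pixel units with
x = column and y = row, so a pixel (r, c) has its centre at (c + 0.5,
r + 0.5). Areas are in square metres (pixel count times pixel_size**2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = ["RasterStack", "Annotation", "AnnotationSet", "BASE_BANDS", "centroid_pixel"]

BASE_BANDS = ("red", "green", "blue", "nir")


@dataclass
class RasterStack:
    """Multiband grid; each band may sit at the base resolution or coarser.

    resolution_factor maps band name -> integer factor (1 = base grid,
    2 = a grid with half the rows/cols, e.g. a canopy-height band).
    """

    bands: dict[str, np.ndarray]
    resolution_factor: dict[str, int]
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        base = self.base_shape
        for name, arr in self.bands.items():
            f = self.resolution_factor.get(name, 1)
            expected = (base[0] // f, base[1] // f)
            if arr.shape != expected:
                raise ValueError(
                    f"band {name!r} has shape {arr.shape}, expected {expected} "
                    f"for resolution factor {f}"
                )

    @property
    def base_shape(self) -> tuple[int, int]:
        for name, arr in self.bands.items():
            if self.resolution_factor.get(name, 1) == 1:
                return arr.shape
        raise ValueError("raster has no base-resolution band")

    def stack(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        """Stack same-resolution bands into a (C, H, W) array."""
        factors = {self.resolution_factor.get(n, 1) for n in names}
        if len(factors) != 1:
            raise ValueError("cannot stack bands with mixed resolutions")
        return np.stack([np.asarray(self.bands[n], dtype=np.float64) for n in names])


@dataclass
class Annotation:
    """One crown delineation: polygon in pixel coords plus derived fields."""

    polygon: Polygon
    centroid_px: tuple[int, int]  # (row, col), nearest-pixel rounding
    area_m2: float
    apex_height_m: float | None = None


@dataclass
class AnnotationSet:
    annotations: list[Annotation] = field(default_factory=list)
    pixel_size_m: float = 1.0

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)

    def centroids(self) -> np.ndarray:
        """(n, 2) integer array of (row, col) centroid pixels."""
        if not self.annotations:
            return np.zeros((0, 2), dtype=int)
        return np.array([a.centroid_px for a in self.annotations], dtype=int)


def centroid_pixel(polygon: Polygon) -> tuple[int, int]:
    """Area centroid of a polygon rounded to the nearest pixel (row, col)."""
    c = polygon.centroid
    # floor(v + 0.5): round-half-up, avoiding banker's rounding surprises
    return (int(np.floor(c.y + 0.5)), int(np.floor(c.x + 0.5)))
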