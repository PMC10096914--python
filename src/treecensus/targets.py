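"""Training targets derived from crown annotations.

Three targets drive the multi-task network:

* a binary segmentation mask (crown pixels = 1),
* a gap-weight map that up-weights the narrow background corridors
  between adjacent crowns, forcing the model to keep touching crowns
  separated, and
* a density map in which every tree contributes one unit of mass via a
  truncated, normalised Gaussian kernel centred on its crown centroid —
  so the integral of the map is the tree count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .containers import AnnotationSet

__all__ = [
    "DensityConfig",
    "truncated_gaussian_kernel",
    "make_density_map",
    "rasterize_crowns",
    "make_gap_map",
    "make_weight_map",
]


@dataclass(frozen=True)
class DensityConfig:
    """Kernel parameters: SD sigma and truncation half-width M (side 2M+1).

    Defaults give the 15x15, sigma=4 kernel used throughout.
    """

    sigma: float = 4.0
    half_width: int = 7

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")


def truncated_gaussian_kernel(cfg: DensityConfig = DensityConfig()) -> np.ndarray:
    """Sampled truncated Gaussian kernel, normalised to unit sum.

    Entry (i, j) on the (2M+1)^2 support is
    exp(-((i-M)^2 + (j-M)^2) / (2 sigma^2)) divided by the sum of the
    unnormalised entries, so the kernel carries exactly one tree of mass.
    """
    m = cfg.half_width
    r = np.arange(-m, m + 1, dtype=np.float64)
    g = np.exp(-(r[:, None] ** 2 + r[None, :] ** 2) / (2.0 * cfg.sigma ** 2))
    return g / g.sum()


def make_density_map(
    annotations: AnnotationSet,
    shape: tuple[int, int],
    cfg: DensityConfig = DensityConfig(),
) -> np.ndarray:
    """Sum of unit-mass kernels centred on the annotation centroids.

    Kernels are evaluated only at in-image pixels: a kernel whose support
    crosses the image border is clipped and its off-image mass lost, so
    the count-equals-integral identity holds exactly only for centroids
    at least M pixels from every border.
    """
    h, w = shape
    m = cfg.half_width
    kernel = truncated_gaussian_kernel(cfg)
    density = np.zeros(shape, dtype=np.float64)
    for idx, ann in enumerate(annotations):
        r, c = ann.centroid_px
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(
                f"annotation {idx}: centroid ({r}, {c}) outside image of shape {shape}"
            )
        r0, r1 = max(r - m, 0), min(r + m + 1, h)
        c0, c1 = max(c - m, 0), min(c + m + 1, w)
        density[r0:r1, c0:c1] += kernel[r0 - r + m : r1 - r + m, c0 - c + m : c1 - c + m]
    return density


def _polygon_mask(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask: pixel is True iff its centre lies inside the polygon."""
    h, w = shape
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)) + 1, w)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)) + 1, h)
    mask = np.zeros(shape, dtype=bool)
    if c0 >= c1 or r0 >= r1:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    inside = shapely.contains_xy(polygon, cols.ravel() + 0.5, rows.ravel() + 0.5)
    mask[r0:r1, c0:c1] = inside.reshape(rows.shape)
    return mask


def rasterize_crowns(annotations: AnnotationSet, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask with ones where a pixel centre falls inside any crown."""
    mask = np.zeros(shape, dtype=np.uint8)
    for idx, ann in enumerate(annotations):
        if not ann.polygon.is_valid:
            raise ValueError(f"annotation {idx}: invalid polygon")
        mask |= _polygon_mask(ann.polygon, shape).astype(np.uint8)
    return mask


def make_gap_map(
    annotations: AnnotationSet,
    shape: tuple[int, int],
    gap_radius_px: int = 3,
) -> np.ndarray:
    """Background pixels lying between at least two nearby crowns.

    A background pixel is a gap pixel iff it is covered by the disc
    dilation (radius gap_radius_px) of two or more distinct crowns; crown
    pixels themselves are never gaps. The rule is symmetric in the crowns,
    so the map is invariant under crown relabelling.
    """
    if gap_radius_px < 1:
        raise ValueError("gap_radius_px must be >= 1")
    structure = disk(gap_radius_px)
    coverage = np.zeros(shape, dtype=np.int32)
    crown_any = np.zeros(shape, dtype=bool)
    for ann in annotations:
        m = _polygon_mask(ann.polygon, shape)
        crown_any |= m
        if m.any():
            coverage += binary_dilation(m, structure=structure)
    return ((coverage >= 2) & ~crown_any).astype(np.uint8)


def make_weight_map(gaps: np.ndarray, gap_weight: float = 5.0) -> np.ndarray:
    """Pixel weights for the Tversky loss: gap pixels get gap_weight, rest 1."""
    if gap_weight < 1:
        raise ValueError("gap_weight must be >= 1")
    return np.where(gaps.astype(bool), float(gap_weight), 1.0)
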