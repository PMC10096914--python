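"""Plot-level evaluation against field-inventory tree counts.

Field inventories count stems on concentric circular plots: the Danish
design uses radii 3.5 / 10 / 15 m with size-class (dbh) rules per
circle, the Finnish design a single 12.62-m circle. Counts from
different circles are made comparable by area-ratio extrapolation under
the even-stem-distribution assumption: N trees observed on area A1
extrapolate to N * A2 / A1 on area A2. Plot-level agreement is
summarised by the relative bias (positive = overprediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infer import TreeRecord, count_from_density
from .metrics import relative_bias

__all__ = [
    "PlotSpec",
    "danish_design",
    "finnish_design",
    "extrapolate_count",
    "predicted_plot_count",
    "danish_reference_counts",
    "evaluate_plots",
]


@dataclass(frozen=True)
class PlotSpec:
    """Concentric-circle plot: centre plus (radius_m, size-class rule) pairs."""

    center: tuple[float, float]  # (row, col) in pixels of the evaluated raster
    circles: tuple[tuple[float, str], ...]

    def __post_init__(self):
        radii = [r for r, _ in self.circles]
        if not radii or any(r <= 0 for r in radii):
            raise ValueError("circle radii must be positive")
        if sorted(radii) != radii or len(set(radii)) != len(radii):
            raise ValueError("circle radii must be strictly increasing")

    @property
    def max_radius_m(self) -> float:
        return self.circles[-1][0]


def danish_design(center: tuple[float, float]) -> PlotSpec:
    """3.5 m (all trees > 1.3 m tall), 10 m (dbh > 10 cm), 15 m (dbh > 40 cm)."""
    return PlotSpec(center=center, circles=(
        (3.5, "height>1.3m"), (10.0, "dbh>10cm"), (15.0, "dbh>40cm"),
    ))


def finnish_design(center: tuple[float, float]) -> PlotSpec:
    """Single 12.62-m circle, all grown-up trees counted exhaustively."""
    return PlotSpec(center=center, circles=((12.62, "all"),))


def extrapolate_count(n: float, area_1: float, area_2: float) -> float:
    """Extrapolate N trees from area A1 to area A2: N * A2 / A1."""
    if area_1 <= 0:
        raise ValueError("source area must be positive")
    return n * area_2 / area_1


def _disc_mask(shape: tuple[int, int], center: tuple[float, float],
               radius_px: float) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return ((rows + 0.5 - center[0]) ** 2 + (cols + 0.5 - center[1]) ** 2) < radius_px ** 2


def predicted_plot_count(source, plot: PlotSpec, pixel_size_m: float,
                         mode: str = "density", radius_m: float | None = None) -> float:
    """Predicted tree count inside one plot circle.

    ``source`` is a density grid (mode='density': the density is
    integrated over the disc) or a list of TreeRecords
    (mode='enumeration': records whose centroid lies strictly inside the
    circle are counted). ``radius_m`` defaults to the outermost circle.
    """
    radius = plot.max_radius_m if radius_m is None else radius_m
    radius_px = radius / pixel_size_m
    if mode == "density":
        density = np.asarray(source, dtype=np.float64)
        h, w = density.shape
        if not (0 <= plot.center[0] < h and 0 <= plot.center[1] < w):
            raise ValueError("plot centre outside the raster extent")
        if (plot.center[0] - radius_px < 0 or plot.center[0] + radius_px > h
                or plot.center[1] - radius_px < 0 or plot.center[1] + radius_px > w):
            raise ValueError("plot circle extends beyond the raster extent")
        return count_from_density(density, _disc_mask(density.shape, plot.center, radius_px))
    if mode == "enumeration":
        n = 0
        for rec in source:
            d = np.hypot(rec.centroid[0] - plot.center[0], rec.centroid[1] - plot.center[1])
            if d < radius_px:  # strict inequality at the boundary
                n += 1
        return float(n)
    raise ValueError("mode must be 'density' or 'enumeration'")


def danish_reference_counts(n_mid_dbh10_40: float, n_large_dbh40: float) -> dict[str, float]:
    """Reference counts for dbh > 10 cm trees from the Danish circle design.

    ``n_mid_dbh10_40``: trees with 10 < dbh <= 40 cm counted exhaustively
    in the 10-m circle. ``n_large_dbh40``: trees with dbh > 40 cm counted
    exhaustively in the full 15-m circle. Two area-ratio (2.25 = (15/10)^2)
    reconstructions are returned:

    * 'in_15m' — extrapolate the mid-size trees out to 15 m;
    * 'in_10m' — remove the share of large trees outside 10 m.
    """
    ratio = (15.0 / 10.0) ** 2
    return {
        "in_15m": extrapolate_count(n_mid_dbh10_40, 1.0, ratio) + n_large_dbh40,
        "in_10m": n_mid_dbh10_40 + n_large_dbh40 / ratio,
    }


def evaluate_plots(pred_counts, field_counts, grouping=None) -> pd.DataFrame:
    """Relative bias per group of plots.

    pred_counts / field_counts: aligned sequences (or dicts keyed by plot
    id); grouping: optional per-plot labels (e.g. forest type). Returns a
    table with one row per group plus an 'all' row.
    """
    if isinstance(pred_counts, dict):
        ids = sorted(pred_counts)
        if set(ids) != set(field_counts):
            raise ValueError("plot ids of predictions and field counts differ")
        pred = np.array([pred_counts[i] for i in ids], dtype=np.float64)
        ref = np.array([field_counts[i] for i in ids], dtype=np.float64)
        groups = None if grouping is None else [grouping[i] for i in ids]
    else:
        pred = np.asarray(pred_counts, dtype=np.float64)
        ref = np.asarray(field_counts, dtype=np.float64)
        groups = list(grouping) if grouping is not None else None
    if pred.shape != ref.shape:
        raise ValueError("prediction and field count tables must align")

    rows = [{"group": "all", "n_plots": len(ref),
             "relative_bias": relative_bias(ref, pred)}]
    if groups is not None:
        for g in sorted(set(groups)):
            sel = np.array([x == g for x in groups])
            rows.append({"group": g, "n_plots": int(sel.sum()),
                         "relative_bias": relative_bias(ref[sel], pred[sel])})
    return pd.DataFrame(rows)
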