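"""File I/O: multiband TIFF rasters and GeoJSON crown polygons.

Rasters are written as plain (Geo)TIFFs via tifffile with the pixel size
recorded in the resolution tags; annotations and per-tree records as
GeoJSON FeatureCollections with per-feature properties. Coordinates are
pixel coordinates (x = column, y = row) unless the caller supplies an
origin/pixel-size transform.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import shape as shapely_shape, mapping

from .containers import Annotation, AnnotationSet, RasterStack, centroid_pixel

__all__ = [
    "write_raster", "read_raster", "write_scene", "read_scene",
    "write_annotations_geojson", "read_annotations_geojson",
    "write_records_geojson",
]


def write_raster(path, array: np.ndarray, pixel_size_m: float) -> None:
    """Write a single- or multi-band grid ((H,W) or (C,H,W)) as TIFF."""
    arr = np.asarray(array)
    res = 1.0 / pixel_size_m
    tifffile.imwrite(path, arr, resolution=(res, res),
                     metadata={"pixel_size_m": pixel_size_m})


def read_raster(path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta = tif.shaped_metadata or tif.imagej_metadata or {}
        if isinstance(meta, (list, tuple)):
            meta = meta[0] if meta else {}
        px = float(meta.get("pixel_size_m", 1.0))
    return arr, px


def write_scene(directory, raster: RasterStack, base_bands=("red", "green", "blue", "nir"),
                height_band: str | None = "height") -> None:
    """Write a scene as image.tif (C,H,W base bands) + height.tif (coarse)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_raster(directory / "image.tif", raster.stack(base_bands), raster.pixel_size_m)
    if height_band and height_band in raster.bands:
        f = raster.resolution_factor.get(height_band, 1)
        write_raster(directory / "height.tif", raster.bands[height_band],
                     raster.pixel_size_m * f)


def read_scene(directory, base_bands=("red", "green", "blue", "nir")) -> RasterStack:
    directory = Path(directory)
    image, px = read_raster(directory / "image.tif")
    bands = {name: image[i] for i, name in enumerate(base_bands)}
    factors = {name: 1 for name in base_bands}
    height_path = directory / "height.tif"
    if height_path.exists():
        height, hpx = read_raster(height_path)
        bands["height"] = height
        factors["height"] = int(round(hpx / px))
    return RasterStack(bands=bands, resolution_factor=factors, pixel_size_m=px)


def write_annotations_geojson(path, annotations: AnnotationSet) -> None:
    features = []
    for i, ann in enumerate(annotations):
        props = {"id": i, "area_m2": ann.area_m2}
        if ann.apex_height_m is not None:
            props["apex_height_m"] = ann.apex_height_m
        features.append({"type": "Feature", "geometry": mapping(ann.polygon),
                         "properties": props})
    collection = {"type": "FeatureCollection",
                  "properties": {"pixel_size_m": annotations.pixel_size_m},
                  "features": features}
    Path(path).write_text(json.dumps(collection))


def read_annotations_geojson(path) -> AnnotationSet:
    data = json.loads(Path(path).read_text())
    px = float(data.get("properties", {}).get("pixel_size_m", 1.0))
    anns = []
    for feat in data["features"]:
        poly = shapely_shape(feat["geometry"])
        props = feat.get("properties", {})
        anns.append(Annotation(
            polygon=poly,
            centroid_px=centroid_pixel(poly),
            area_m2=float(props.get("area_m2", poly.area * px ** 2)),
            apex_height_m=props.get("apex_height_m"),
        ))
    return AnnotationSet(annotations=anns, pixel_size_m=px)


def write_records_geojson(path, records, pixel_size_m: float = 1.0) -> None:
    """Per-tree records (id, area_m2, height_m, nir_max) as GeoJSON polygons."""
    features = []
    for rec in records:
        features.append({
            "type": "Feature",
            "geometry": mapping(rec.polygon()),
            "properties": {"id": rec.id, "area_m2": rec.area_s,
                           "height_m": rec.height_m, "nir_max": rec.nir_max},
        })
    collection = {"type": "FeatureCollection",
                  "properties": {"pixel_size_m": pixel_size_m},
                  "features": features}
    Path(path).write_text(json.dumps(collection))
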