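"""Georeferenced single-band rasters and vector layers.

Rasters are stored as plain numpy grids with an explicit validity mask and
just enough georeferencing (pixel size, EPSG code, upper-left origin) to
support window arithmetic in meters and raster/vector overlay.  On disk the
format is single-band float32 GeoTIFF: the standard GeoTIFF tags
(ModelPixelScale 33550, ModelTiepoint 33922, GeoKeyDirectory 34735) plus
GDAL's nodata tag 42113 are written and read through :mod:`tifffile`.

Conventions: row-major ``(row, col)`` indexing with ``(0, 0)`` the upper-left
pixel; ``origin`` is the map coordinate of the grid's upper-left *corner*;
pixel centers sit half a pixel inside; the y axis decreases with row (north
up).  All geometry must live in one projected CRS in meters — window sizes
and buffer widths are specified in meters, so geographic (degree) rasters
are rejected at read time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "ReflectanceRaster",
    "VectorLayer",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "apply_mask",
    "enhance_contrast",
    "compute_ndvi",
]

# GeoTIFF / GeoKey constants
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113
_KEY_GT_MODEL_TYPE = 1024
_KEY_GT_RASTER_TYPE = 1025
_KEY_PROJECTED_CS_TYPE = 3072
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2

#: EPSG codes that are geographic (lat/lon) even if a file mislabels the
#: model type; kept tiny on purpose — full CRS handling is out of scope.
_GEOGRAPHIC_EPSG = {4326, 4258, 4267, 4269}


@dataclass
class ReflectanceRaster:
    """A single-band georeferenced grid with a validity mask.

    Parameters
    ----------
    values
        2-D float array of reflectance (dimensionless).  Finite wherever
        ``valid_mask`` is true; content of invalid pixels is unspecified.
    valid_mask
        2-D boolean array, same shape; ``True`` marks usable pixels.
    pixel_size
        Ground sampling distance ``(x, y)`` in meters per pixel.
    crs_id
        EPSG code of the projected CRS.
    origin
        Map coordinates ``(x, y)`` of the upper-left corner of pixel (0, 0).
    acquisition_label
        Free-text date/epoch tag carried through the pipeline.
    meta
        Free-form side-channel (e.g. synthetic-scene feature labels); never
        serialized.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    pixel_size: tuple[float, float] = (10.0, 10.0)
    crs_id: int = 32636
    origin: tuple[float, float] = (0.0, 0.0)
    acquisition_label: str = ""
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.valid_mask.shape}"
            )
        if not (self.pixel_size[0] > 0 and self.pixel_size[1] > 0):
            raise ValueError("pixel_size must be positive in both axes")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("values must be finite wherever valid_mask is true")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates of pixel centers as 1-D arrays ``(x_of_col, y_of_row)``."""
        nrow, ncol = self.shape
        px, py = self.pixel_size
        x = self.origin[0] + (np.arange(ncol) + 0.5) * px
        y = self.origin[1] - (np.arange(nrow) + 0.5) * py
        return x, y

    def with_values(self, values: np.ndarray, valid_mask: np.ndarray | None = None) -> "ReflectanceRaster":
        """Copy of this raster with new values (and optionally a new mask)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            valid_mask=self.valid_mask.copy() if valid_mask is None else valid_mask,
            meta=dict(self.meta),
        )


@dataclass
class VectorLayer:
    """Labeled shapely geometries (polygons or polylines) in the raster CRS."""

    geometries: list[BaseGeometry]
    labels: list[str]
    crs_id: int = 32636

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.labels):
            raise ValueError("one label per geometry required")
        for geom, label in zip(self.geometries, self.labels):
            if geom.is_empty:
                raise ValueError(f"geometry {label!r} is empty")
            if not geom.is_valid:
                raise ValueError(f"geometry {label!r} is invalid")

    def __getitem__(self, label: str) -> BaseGeometry:
        try:
            return self.geometries[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None


def write_raster(r: ReflectanceRaster, path: str | Path, nodata: float = float("nan")) -> Path:
    """Write a raster as single-band float32 GeoTIFF.

    Invalid pixels are filled with ``nodata`` (NaN by default) and the value
    is recorded in GDAL's nodata tag so any GeoTIFF reader recovers the mask.
    """
    path = Path(path)
    data = r.values.astype(np.float32).copy()
    data[~r.valid_mask] = np.float32(nodata)
    px, py = r.pixel_size
    geokeys = (
        1, 1, 0, 3,
        _KEY_GT_MODEL_TYPE, 0, 1, _MODEL_TYPE_PROJECTED,
        _KEY_GT_RASTER_TYPE, 0, 1, 1,  # PixelIsArea
        _KEY_PROJECTED_CS_TYPE, 0, 1, int(r.crs_id),
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (float(px), float(py), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(r.origin[0]), float(r.origin[1]), 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(nodata))),
    ]
    tifffile.imwrite(
        path,
        data,
        extratags=extratags,
        metadata=None,
        description=r.acquisition_label or None,
    )
    return path


def read_raster(path: str | Path, band_index: int = 1) -> ReflectanceRaster:
    """Read one band of a georeferenced raster.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    rasters in a geographic (degree) CRS — reproject to a projected CRS in
    meters first, window sizes are metric.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=float)
        if data.ndim == 3:
            if not 1 <= band_index <= data.shape[0]:
                raise ValueError(f"band_index {band_index} out of range 1..{data.shape[0]}")
            data = data[band_index - 1]
        elif band_index != 1:
            raise ValueError(f"band_index {band_index} out of range for single-band raster")
        tags = page.tags

        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else None
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else None
        if scale is None or tiepoint is None:
            raise ValueError(f"{path} has no GeoTIFF geotransform tags")
        px, py = float(scale[0]), float(scale[1])
        # tiepoint maps raster (i, j, k) -> model (x, y, z); with PixelIsArea
        # and a (0,0) raster point the model point is the UL corner.
        origin = (
            float(tiepoint[3]) - float(tiepoint[0]) * px,
            float(tiepoint[4]) + float(tiepoint[1]) * py,
        )

        crs_id = 0
        model_type = _MODEL_TYPE_PROJECTED
        if _TAG_GEO_KEY_DIRECTORY in tags:
            keys = tags[_TAG_GEO_KEY_DIRECTORY].value
            for k in range(4, len(keys) - 3, 4):
                key_id, _, _, value = keys[k : k + 4]
                if key_id == _KEY_GT_MODEL_TYPE:
                    model_type = value
                elif key_id in (_KEY_PROJECTED_CS_TYPE, 2048):
                    crs_id = int(value)
        if model_type == _MODEL_TYPE_GEOGRAPHIC or crs_id in _GEOGRAPHIC_EPSG:
            raise ValueError(
                f"{path} is in a geographic CRS (EPSG:{crs_id}); reproject to a "
                "projected CRS in meters before use (window sizes are metric)"
            )

        nodata = None
        if _TAG_GDAL_NODATA in tags:
            try:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            except (TypeError, ValueError):
                nodata = None

        label = ""
        if 270 in tags and tags[270].value:  # ImageDescription
            label = str(tags[270].value)

    mask = np.isfinite(data)
    if nodata is not None and not np.isnan(nodata):
        mask &= data != nodata
    return ReflectanceRaster(
        values=data,
        valid_mask=mask,
        pixel_size=(px, py),
        crs_id=crs_id,
        origin=origin,
        acquisition_label=label,
    )


def write_vector(layer: VectorLayer, path: str | Path) -> Path:
    """Write a VectorLayer as a GeoJSON FeatureCollection."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "properties": {"label": label},
            "geometry": mapping(geom),
        }
        for geom, label in zip(layer.geometries, layer.labels)
    ]
    doc = {
        "type": "FeatureCollection",
        "crs_id": layer.crs_id,
        "features": features,
    }
    path.write_text(json.dumps(doc))
    return path


def read_vector(path: str | Path) -> VectorLayer:
    """Read a GeoJSON FeatureCollection into a VectorLayer."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    geoms, labels = [], []
    for i, feat in enumerate(doc.get("features", [])):
        geoms.append(shape(feat["geometry"]))
        labels.append(str(feat.get("properties", {}).get("label", i)))
    return VectorLayer(geoms, labels, crs_id=int(doc.get("crs_id", 0)))


def apply_mask(r: ReflectanceRaster, mask: np.ndarray | ReflectanceRaster) -> ReflectanceRaster:
    """Intersect the raster's validity mask with another mask.

    ``mask`` may be a boolean grid or a raster whose valid_mask is used
    (e.g. a cloud/shadow mask product where True = clear).  Values are
    unchanged; the valid set never grows.
    """
    grid = mask.valid_mask if isinstance(mask, ReflectanceRaster) else np.asarray(mask, dtype=bool)
    if grid.shape != r.shape:
        raise ValueError(f"mask shape {grid.shape} != raster shape {r.shape}")
    return r.with_values(r.values.copy(), valid_mask=r.valid_mask & grid)


def enhance_contrast(
    r: ReflectanceRaster, lower_pct: float = 2.0, upper_pct: float = 98.0
) -> ReflectanceRaster:
    """Percentile linear stretch of valid values to [0, 1], clipping outside.

    The ``lower_pct`` percentile of valid values maps to 0 and the
    ``upper_pct`` percentile to 1; values outside are clipped.  Invalid
    pixels are untouched.  A constant image has no defined stretch and
    raises ``ValueError``.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    valid = r.values[r.valid_mask]
    if valid.size < 2 or np.unique(valid).size < 2:
        raise ValueError("contrast stretch undefined on a constant image")
    lo, hi = np.percentile(valid, [lower_pct, upper_pct])
    if hi <= lo:
        raise ValueError("degenerate percentile range; widen the percentiles")
    out = r.values.copy()
    stretched = np.clip((r.values - lo) / (hi - lo), 0.0, 1.0)
    out[r.valid_mask] = stretched[r.valid_mask]
    return r.with_values(out)


def compute_ndvi(red: ReflectanceRaster, nir: ReflectanceRaster) -> ReflectanceRaster:
    """Normalized difference vegetation index (NIR − Red)/(NIR + Red).

    Pixels where the denominator is zero are marked invalid.  Used as an
    optional alternative input layer to the contour chain and for temporal
    stability comparisons against the contour-density maps.
    """
    if red.shape != nir.shape:
        raise ValueError(f"grid mismatch {red.shape} vs {nir.shape}")
    if red.crs_id != nir.crs_id:
        raise ValueError("CRS mismatch between red and nir")
    denom = nir.values + red.values
    mask = red.valid_mask & nir.valid_mask & (denom != 0)
    out = np.zeros_like(red.values)
    np.divide(nir.values - red.values, denom, out=out, where=denom != 0)
    return red.with_values(out, valid_mask=mask)
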