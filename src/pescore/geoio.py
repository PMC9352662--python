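"""GeoTIFF and GeoJSON input/output.

Rasters are written as single-band float32 GeoTIFFs (north-up, WGS84,
pixel-is-area) with the standard GeoTIFF georeferencing tags and the GDAL
nodata convention, readable by any GIS stack.  Range maps travel as GeoJSON
FeatureCollections with one feature per seasonal polygon.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .grid import GridSpec

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GTModelType=Geographic, GTRasterType=PixelIsArea, GeographicType=WGS84
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)
_NODATA = -9999.0


def write_geotiff(path: str | Path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a grid of values as a georeferenced float32 GeoTIFF (NaN -> nodata)."""
    path = Path(path)
    data = np.asarray(values, dtype=np.float32).copy()
    data[~np.isfinite(data)] = _NODATA
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.resolution, grid.resolution, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.lon_min, grid.lat_max, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
        (_TAG_GDAL_NODATA, "s", 0, str(_NODATA)),
    ]
    try:
        tifffile.imwrite(path, data, extratags=extratags)
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing GeoTIFF {path}: {exc}") from exc


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a GeoTIFF written by :func:`write_geotiff` (nodata -> NaN)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = page.tags[_TAG_MODEL_TIEPOINT].value
        nodata = float(page.tags[_TAG_GDAL_NODATA].value)
    data[data == nodata] = np.nan
    grid = GridSpec(
        resolution=float(scale[0]),
        lon_min=float(tiepoint[3]),
        lat_max=float(tiepoint[4]),
        n_rows=data.shape[0],
        n_cols=data.shape[1],
    )
    return data, grid


def write_geojson(path: str | Path, features: list[dict]) -> None:
    """Write features ({'geometry': shapely geom, 'properties': {...}}) as GeoJSON."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f["geometry"]),
                "properties": f["properties"],
            }
            for f in features
        ],
    }
    path = Path(path)
    try:
        path.write_text(json.dumps(collection))
    except OSError as exc:  # pragma: no cover
        raise OSError(f"failed writing GeoJSON {path}: {exc}") from exc


def read_geojson(path: str | Path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into shapely geometries + properties."""
    collection = json.loads(Path(path).read_text())
    out: list[dict[str, BaseGeometry | dict]] = []
    for feat in collection["features"]:
        out.append(
            {"geometry": shape(feat["geometry"]), "properties": feat["properties"]}
        )
    return out
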