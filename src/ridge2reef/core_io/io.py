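"""Raster and vector file I/O.

Rasters are stored as single-band TIFF files with the georeferencing
metadata (cell size, origin, nodata, CRS) serialized as JSON in the TIFF
image-description tag.  Vectors travel as GeoJSON.  Values are written
float32 (continuous) or int32 (class codes) and round-trip bit-exact.
"""

from __future__ import annotations

import json
import os
from typing import Any

import numpy as np
import tifffile
from scipy.ndimage import map_coordinates

from ridge2reef.core_io.grid import Grid


class ConfigurationError(ValueError):
    pass


def write_grid(grid: Grid, path: str | os.PathLike) -> None:
    """Write ``grid`` to ``path`` as a georeferenced single-band TIFF."""
    path = os.fspath(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    if grid.is_class_grid:
        values = grid.values.astype(np.int32)
        nodata = None if np.isnan(grid.nodata) else int(grid.nodata)
    else:
        values = grid.values.astype(np.float32)
        nodata = None if np.isnan(grid.nodata) else float(grid.nodata)
    meta = {
        "cell_size": float(grid.cell_size),
        "origin": [float(grid.origin[0]), float(grid.origin[1])],
        "nodata": nodata,
        "crs": grid.crs,
    }
    tifffile.imwrite(path, values, description=json.dumps(meta))


def read_grid(
    path: str | os.PathLike,
    target_cell_size: float | None = None,
    expect_crs: str | None = None,
) -> Grid:
    """Read a single-band raster, optionally resampling to a new cell size.

    Continuous grids resample bilinearly, class-code grids by nearest
    neighbor.  ``expect_crs`` guards against mixing layers from different
    coordinate systems.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta: dict[str, Any] = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if values.ndim != 2:
        raise ValueError(f"expected a single-band raster, got shape {values.shape}")
    nodata = meta.get("nodata")
    grid = Grid(
        values=values,
        cell_size=float(meta.get("cell_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=float("nan") if nodata is None else float(nodata),
        crs=str(meta.get("crs", "local-meters")),
    )
    if expect_crs is not None and grid.crs != expect_crs:
        raise ConfigurationError(
            f"CRS mismatch: {path} has {grid.crs!r}, expected {expect_crs!r}"
        )
    if not grid.is_class_grid:
        vals = grid.values.astype(float)
        if not np.isnan(grid.nodata):
            vals[vals == grid.nodata] = np.nan
        grid = grid.like(vals)
    if target_cell_size is not None and target_cell_size != grid.cell_size:
        grid = resample(grid, target_cell_size)
    return grid


def resample(grid: Grid, target_cell_size: float) -> Grid:
    """Resample to ``target_cell_size``: bilinear for continuous values,
    nearest neighbor for class codes."""
    if target_cell_size <= 0:
        raise ValueError("target_cell_size must be > 0")
    factor = target_cell_size / grid.cell_size
    nrow = max(1, int(round(grid.shape[0] / factor)))
    ncol = max(1, int(round(grid.shape[1] / factor)))
    # fractional source indices of the new cell centers
    rows = (np.arange(nrow) + 0.5) * factor - 0.5
    cols = (np.arange(ncol) + 0.5) * factor - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    order = 0 if grid.is_class_grid else 1
    out = map_coordinates(
        grid.values.astype(float), [rr, cc], order=order, mode="nearest"
    )
    if grid.is_class_grid:
        out = out.astype(grid.values.dtype)
    return Grid(out, target_cell_size, grid.origin, grid.nodata, grid.crs)


# -- GeoJSON ---------------------------------------------------------------


def write_points_geojson(
    path: str | os.PathLike,
    points: list[tuple[float, float]],
    properties: list[dict] | None = None,
) -> None:
    feats = []
    for i, (x, y) in enumerate(points):
        props = properties[i] if properties else {}
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def read_points_geojson(path: str | os.PathLike) -> list[tuple[tuple[float, float], dict]]:
    with open(path) as fh:
        data = json.load(fh)
    out = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Point":
            continue
        x, y = geom["coordinates"][:2]
        out.append(((float(x), float(y)), feat.get("properties", {})))
    return out


def write_geojson_geometry(path: str | os.PathLike, geometry, properties: dict | None = None) -> None:
    """Write a single shapely geometry as a one-feature GeoJSON file."""
    from shapely.geometry import mapping

    feature = {
        "type": "Feature",
        "geometry": mapping(geometry),
        "properties": properties or {},
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)
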