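"""Minimal single-band GeoTIFF reader/writer for north-up geographic grids.

Only the subset of GeoTIFF needed here is supported: one band, a
``ModelPixelScale`` + single ``ModelTiepoint`` georeference (the layout
WorldClim-style tiles use), and an optional ``GDAL_NODATA`` value.  Grids
are assumed north-up in geographic coordinates (longitude/latitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

TAG_MODEL_PIXEL_SCALE = 33550
TAG_MODEL_TIEPOINT = 33922
TAG_GEO_KEY_DIRECTORY = 34735
TAG_GDAL_NODATA = 42113

# GTModelType=geographic, GTRasterType=PixelIsArea, GeographicType=WGS84
_GEO_KEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)

#: mean Earth radius in meters, used for great-circle cell selection
EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class GridGeoref:
    """North-up affine georeference: pixel size and upper-left corner."""

    west: float
    north: float
    xres: float
    yres: float
    ncols: int
    nrows: int

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.xres

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.yres

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside."""
        col = int(math.floor((lon - self.west) / self.xres))
        row = int(math.floor((self.north - lat) / self.yres))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.west + (col + 0.5) * self.xres,
            self.north - (row + 0.5) * self.yres,
        )


@dataclass(frozen=True)
class Raster:
    """A single-band grid with georeference and optional NoData."""

    data: np.ndarray
    georef: GridGeoref
    nodata: float | None = None

    def values_with_validity(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (float array, boolean validity mask honoring NoData/NaN)."""
        arr = self.data.astype(float)
        valid = np.isfinite(arr)
        if self.nodata is not None:
            valid &= arr != self.nodata
        return arr, valid


def write_geotiff(
    path: str | Path,
    data: np.ndarray,
    georef: GridGeoref,
    nodata: float | None = None,
) -> None:
    """Write ``data`` as a georeferenced single-band GeoTIFF.

    Floating-point input keeps its precision (float64 grids stay float64);
    anything else is stored as float32.
    """
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    if data.shape != (georef.nrows, georef.ncols):
        raise ValueError(
            f"data shape {data.shape} does not match georef "
            f"({georef.nrows}, {georef.ncols})"
        )
    extratags = [
        (TAG_MODEL_PIXEL_SCALE, "d", 3, (georef.xres, georef.yres, 0.0)),
        (
            TAG_MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, georef.west, georef.north, 0.0),
        ),
        (TAG_GEO_KEY_DIRECTORY, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]
    if nodata is not None:
        extratags.append((TAG_GDAL_NODATA, "s", 0, repr(float(nodata))))
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_geotiff(path: str | Path) -> Raster:
    """Read a single-band GeoTIFF written with a pixel-scale georeference."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if TAG_MODEL_PIXEL_SCALE not in tags or TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeference tags")
        sx, sy, _ = tags[TAG_MODEL_PIXEL_SCALE].value
        tie = tags[TAG_MODEL_TIEPOINT].value
        # single tiepoint anchored at raster (0, 0)
        if tie[0] != 0.0 or tie[1] != 0.0:
            raise ValueError(f"{path}: only (0,0)-anchored tiepoints supported")
        nodata: float | None = None
        if TAG_GDAL_NODATA in tags:
            nodata = float(tags[TAG_GDAL_NODATA].value)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    nrows, ncols = data.shape
    georef = GridGeoref(
        west=float(tie[3]),
        north=float(tie[4]),
        xres=float(sx),
        yres=float(sy),
        ncols=ncols,
        nrows=nrows,
    )
    return Raster(data=data, georef=georef, nodata=nodata)


def haversine_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in meters on a spherical Earth."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def sample_point(raster: Raster, lon: float, lat: float) -> float | None:
    """Value of the cell containing (lon, lat); None if outside or NoData."""
    cell = raster.georef.cell_of(lon, lat)
    if cell is None:
        return None
    arr, valid = raster.values_with_validity()
    row, col = cell
    if not valid[row, col]:
        return None
    return float(arr[row, col])


def sample_buffer(
    raster: Raster, lon: float, lat: float, buffer_m: float
) -> float | None:
    """Mean over valid cells whose centers lie within ``buffer_m`` meters.

    A circle of radius ``buffer_m`` around the site in an azimuthal
    equidistant projection centered on the site is exactly the set of
    points within that great-circle distance, so the haversine distance to
    each cell center is the inclusion test.  Returns None when no valid
    cell center falls inside the circle.
    """
    g = raster.georef
    # conservative bounding window in degrees to avoid scanning the grid
    dlat = math.degrees(buffer_m / EARTH_RADIUS_M) * 1.05 + g.yres
    coslat = max(math.cos(math.radians(lat)), 1e-9)
    dlon = dlat / coslat
    row0 = max(0, int(math.floor((g.north - (lat + dlat)) / g.yres)))
    row1 = min(g.nrows, int(math.ceil((g.north - (lat - dlat)) / g.yres)))
    col0 = max(0, int(math.floor(((lon - dlon) - g.west) / g.xres)))
    col1 = min(g.ncols, int(math.ceil(((lon + dlon) - g.west) / g.xres)))
    arr, valid = raster.values_with_validity()
    total = 0.0
    count = 0
    for row in range(row0, row1):
        for col in range(col0, col1):
            if not valid[row, col]:
                continue
            clon, clat = g.cell_center(row, col)
            if haversine_m(lon, lat, clon, clat) <= buffer_m:
                total += float(arr[row, col])
                count += 1
    if count == 0:
        return None
    return total / count
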