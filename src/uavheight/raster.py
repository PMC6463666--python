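"""Georeferenced single-band elevation rasters.

An :class:`ElevationRaster` is a plain 2-D float grid with a north-up affine
georeference (west/north origin, square pixels) in a projected, meter-unit
CRS.  It plays all three raster roles in the pipeline: digital surface model
(DSM), digital terrain model (DTM) and plant height model (PHM).

GeoTIFF I/O is implemented directly on top of :mod:`tifffile` using the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory and
the GDAL nodata tag), which is sufficient for single-band, north-up float32
rasters in an EPSG-coded projected CRS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import shapely
import tifffile
from shapely.geometry.base import BaseGeometry

__all__ = ["ElevationRaster", "GridMismatchError"]

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

_DEFAULT_NODATA = -9999.0
_DEFAULT_CRS = "EPSG:32650"  # UTM 50N, meters


class GridMismatchError(ValueError):
    """Raised when two rasters that must share a grid do not."""


@dataclass
class ElevationRaster:
    """Single-band elevation grid with a north-up affine georeference.

    Parameters
    ----------
    data
        2-D array of elevations in meters; ``nodata`` marks missing pixels.
    x_origin, y_origin
        CRS coordinates of the raster's north-west corner (edge, not pixel
        center).
    pixel_size
        Ground size of one (square) pixel in CRS units; must be > 0.
    nodata
        Sentinel value for missing pixels.
    crs
        EPSG string of a projected, meter-unit CRS.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    pixel_size: float
    nodata: float = _DEFAULT_NODATA
    crs: str = _DEFAULT_CRS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be positive")
        valid = self.values_valid()
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("non-nodata raster values must be finite")

    # ------------------------------------------------------------------ grid
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) edges of the raster extent."""
        ny, nx = self.data.shape
        return (
            self.x_origin,
            self.y_origin - ny * self.pixel_size,
            self.x_origin + nx * self.pixel_size,
            self.y_origin,
        )

    def x_centers(self) -> np.ndarray:
        nx = self.data.shape[1]
        return self.x_origin + (np.arange(nx) + 0.5) * self.pixel_size

    def y_centers(self) -> np.ndarray:
        ny = self.data.shape[0]
        return self.y_origin - (np.arange(ny) + 0.5) * self.pixel_size

    def valid_mask(self) -> np.ndarray:
        return self.data != self.nodata

    def values_valid(self) -> np.ndarray:
        return self.data[self.valid_mask()]

    def same_grid(self, other: "ElevationRaster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
            and np.isclose(self.pixel_size, other.pixel_size)
            and self.crs == other.crs
        )

    def require_same_grid(self, other: "ElevationRaster") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                "rasters do not share grid/CRS "
                f"({self.shape}@{self.pixel_size} vs {other.shape}@{other.pixel_size}); "
                "no silent resampling is performed"
            )

    def like(self, data: np.ndarray) -> "ElevationRaster":
        """New raster with the same georeference but different data."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    # ------------------------------------------------------- polygon queries
    def polygon_mask(self, polygon: BaseGeometry) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of pixels whose *centers* fall inside ``polygon``.

        Only the polygon's bounding box is scanned, so queries on small plot
        polygons stay cheap on large field rasters.
        """
        minx, miny, maxx, maxy = polygon.bounds
        px = self.pixel_size
        c0 = max(int(np.floor((minx - self.x_origin) / px)), 0)
        c1 = min(int(np.ceil((maxx - self.x_origin) / px)), self.data.shape[1])
        r0 = max(int(np.floor((self.y_origin - maxy) / px)), 0)
        r1 = min(int(np.ceil((self.y_origin - miny) / px)), self.data.shape[0])
        if c0 >= c1 or r0 >= r1:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        cols = np.arange(c0, c1)
        rows = np.arange(r0, r1)
        xs = self.x_origin + (cols + 0.5) * px
        ys = self.y_origin - (rows + 0.5) * px
        xx, yy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
        rr, cc = np.nonzero(inside)
        return rows[rr], cols[cc]

    def polygon_values(
        self, polygon: BaseGeometry
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Valid (non-nodata) pixel values inside ``polygon`` with coordinates.

        Returns ``(values, x, y)`` of the pixel centers.
        """
        rows, cols = self.polygon_mask(polygon)
        if rows.size == 0:
            return (np.empty(0),) * 3
        vals = self.data[rows, cols]
        ok = vals != self.nodata
        xs = self.x_origin + (cols[ok] + 0.5) * self.pixel_size
        ys = self.y_origin - (rows[ok] + 0.5) * self.pixel_size
        return vals[ok], xs, ys

    # -------------------------------------------------------------- GeoTIFF
    def to_geotiff(self, path: str | Path) -> None:
        """Write as single-band float32 GeoTIFF with explicit nodata."""
        epsg = int(self.crs.split(":")[1])
        # GeoKeys: model type = projected (1), raster type = PixelIsArea (1),
        # ProjectedCSTypeGeoKey = EPSG code.
        geokeys = (1, 1, 0, 3, 1024, 0, 1, 1, 1025, 0, 1, 1, 3072, 0, 1, epsg)
        extratags = [
            (_TAG_MODEL_PIXEL_SCALE, "d", 3, (self.pixel_size, self.pixel_size, 0.0)),
            (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.x_origin, self.y_origin, 0.0)),
            (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
            (_TAG_GDAL_NODATA, "s", 0, repr(float(self.nodata))),
        ]
        tifffile.imwrite(
            str(path), self.data.astype(np.float32), extratags=extratags
        )

    @classmethod
    def from_geotiff(cls, path: str | Path) -> "ElevationRaster":
        with tifffile.TiffFile(str(path)) as tif:
            page = tif.pages[0]
            data = page.asarray()
            tags = page.tags
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
            nodata = _DEFAULT_NODATA
            if _TAG_GDAL_NODATA in tags:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
            crs = _DEFAULT_CRS
            if _TAG_GEO_KEY_DIRECTORY in tags:
                keys = tags[_TAG_GEO_KEY_DIRECTORY].value
                for i in range(4, len(keys), 4):
                    if keys[i] == 3072:
                        crs = f"EPSG:{keys[i + 3]}"
        if not np.isclose(scale[0], scale[1]):
            raise ValueError("only square pixels are supported")
        return cls(
            data=np.asarray(data, dtype=np.float64),
            x_origin=float(tiepoint[3]),
            y_origin=float(tiepoint[4]),
            pixel_size=float(scale[0]),
            nodata=nodata,
            crs=crs,
        )
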