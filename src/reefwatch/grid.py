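"""Shared raster grid model.

All rasters in this package live on an equidistant cylindrical (plate
carrée) grid: latitude and longitude map linearly to rows and columns,
row 0 is the northernmost row, and every pixel is assigned a fixed
nominal area of 1/16 km² regardless of latitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

#: metres per degree of latitude/longitude used for the nominal grid spacing
M_PER_DEG = 111_320.0

#: nominal area of one 250-m pixel, km²
PIXEL_AREA_KM2 = 1.0 / 16.0


@dataclass(frozen=True)
class Grid:
    """North-up equidistant cylindrical raster grid.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max
        Geographic bounds in degrees.
    pixel_size_m
        Nominal pixel size in metres (default 250).
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    pixel_size_m: float = 250.0

    def __post_init__(self) -> None:
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("grid bounds must satisfy lat_max > lat_min and lon_max > lon_min")

    @property
    def ny(self) -> int:
        return max(1, int(round((self.lat_max - self.lat_min) * M_PER_DEG / self.pixel_size_m)))

    @property
    def nx(self) -> int:
        return max(1, int(round((self.lon_max - self.lon_min) * M_PER_DEG / self.pixel_size_m)))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def dlat(self) -> float:
        return (self.lat_max - self.lat_min) / self.ny

    @property
    def dlon(self) -> float:
        return (self.lon_max - self.lon_min) / self.nx

    def lat_centers(self) -> np.ndarray:
        """Pixel-center latitudes, descending (row 0 = northernmost)."""
        return self.lat_max - (np.arange(self.ny) + 0.5) * self.dlat

    def lon_centers(self) -> np.ndarray:
        """Pixel-center longitudes, ascending."""
        return self.lon_min + (np.arange(self.nx) + 0.5) * self.dlon

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon2d, lat2d) pixel-center coordinate grids, each of ``shape``."""
        lon2d, lat2d = np.meshgrid(self.lon_centers(), self.lat_centers())
        return lon2d, lat2d

    def empty_mask(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=bool)

    def rowcol_to_latlon(self, row: float, col: float) -> tuple[float, float]:
        lat = self.lat_max - (row + 0.5) * self.dlat
        lon = self.lon_min + (col + 0.5) * self.dlon
        return lat, lon


def area_km2(mask: np.ndarray) -> float:
    """Area of a boolean mask under the fixed 1/16 km²-per-pixel rule."""
    return float(np.count_nonzero(mask)) * PIXEL_AREA_KM2


def as_geometry(polygon) -> BaseGeometry:
    """Coerce a polygon-like input to a shapely geometry.

    Accepts shapely geometries, a sequence of (lon, lat) pairs, or a
    sequence of such rings/polygons. ``None`` or an empty sequence maps
    to an empty geometry.
    """
    if polygon is None:
        return Polygon()
    if isinstance(polygon, BaseGeometry):
        return polygon
    seq = list(polygon)
    if not seq:
        return Polygon()
    first = seq[0]
    if isinstance(first, BaseGeometry):
        return shapely.union_all(seq)
    # sequence of coordinate pairs vs sequence of rings
    if isinstance(first, Sequence) and len(first) == 2 and np.isscalar(first[0]):
        return Polygon(seq)
    return MultiPolygon([Polygon(ring) for ring in seq])


def rasterize_polygon(polygon, grid: Grid) -> np.ndarray:
    """Rasterize a polygon onto ``grid`` by pixel-center containment.

    A pixel is set iff its center lies strictly inside the polygon.
    Degenerate (zero-area) polygons yield an empty mask with a warning.
    """
    geom = as_geometry(polygon)
    if geom.is_empty:
        return grid.empty_mask()
    if geom.area == 0:
        warnings.warn("degenerate zero-area polygon rasterizes to an empty mask", stacklevel=2)
        return grid.empty_mask()
    minx, miny, maxx, maxy = geom.bounds
    if maxx < grid.lon_min or minx > grid.lon_max or maxy < grid.lat_min or miny > grid.lat_max:
        warnings.warn("polygon lies entirely outside the grid bounds", stacklevel=2)
        return grid.empty_mask()
    lon2d, lat2d = grid.center_mesh()
    inside = shapely.contains_xy(geom, lon2d.ravel(), lat2d.ravel())
    return inside.reshape(grid.shape)
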