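"""Minimal local map projection for grids and rasters.

The gridding and land-cover sampling steps need planar coordinates in
meters.  Analyses here run on sub-state domains (tens to a couple hundred
kilometers), where a local equirectangular projection about a reference
point is accurate to well under a percent — ample for assigning points to
4 km cells or 30 m raster cells.  The projection is part of the grid/raster
definition so that two fields are only comparable when their CRS matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import EARTH_RADIUS_M

__all__ = ["LocalEquirectangular"]


@dataclass(frozen=True)
class LocalEquirectangular:
    """Plate-carree projection tangent at (lon0, lat0), units meters.

    x = R cos(lat0) (lon - lon0);  y = R (lat - lat0), angles in radians.
    """

    lon0: float
    lat0: float
    radius: float = EARTH_RADIUS_M

    def to_xy(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        k = math.cos(math.radians(self.lat0)) * self.radius
        x = np.radians(lon - self.lon0) * k
        y = np.radians(lat - self.lat0) * self.radius
        return x, y

    def to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        k = math.cos(math.radians(self.lat0)) * self.radius
        lon = self.lon0 + np.degrees(x / k)
        lat = self.lat0 + np.degrees(y / self.radius)
        return lon, lat
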