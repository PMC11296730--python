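"""Land-cover rasters and the square-footprint dominant-class rule.

Burn-type differentiation needs the land cover under each fire.  The
reference product is a 30 m class-coded national raster updated every two
to three years; class codes are grouped into AGRICULTURE (81 pasture/hay,
82 cultivated crops by default), WATER (11), BARREN (31) and OTHER.  A
fire's footprint is modeled as a square of the same area as the burned
area, centered on the reported point; the modal class among raster cells
whose centers fall inside the square is the fire's land cover.

Rasters are stored with a lower-left origin in a projected CRS (row 0 =
southernmost row) and serialized as ESRI ASCII grid text.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from ._proj import LocalEquirectangular
from .records import ACRE_M2

__all__ = [
    "Group",
    "DEFAULT_GROUP_MAP",
    "LandCoverGrid",
    "LandCoverError",
    "vintage_for_year",
    "dominant_land_cover",
]


class Group(str, enum.Enum):
    AGRICULTURE = "AGRICULTURE"
    WATER = "WATER"
    BARREN = "BARREN"
    OTHER = "OTHER"


#: NLCD-style grouping: 81 pasture/hay and 82 cultivated crops as agriculture,
#: 11 open water, 31 barren land.  Everything unmapped is OTHER.
DEFAULT_GROUP_MAP: dict[int, Group] = {
    81: Group.AGRICULTURE,
    82: Group.AGRICULTURE,
    11: Group.WATER,
    31: Group.BARREN,
}


class LandCoverError(ValueError):
    """Raised when a record cannot be placed on the raster."""


@dataclass
class LandCoverGrid:
    """Class-coded raster with lower-left origin.

    ``classes[iy, ix]`` covers the cell whose lower-left corner is
    ``(x0 + ix*cell_size, y0 + iy*cell_size)``; cell centers sit half a cell
    further.  ``crs`` projects WGS84 lon/lat to the raster's x/y meters.
    """

    classes: np.ndarray
    x0: float
    y0: float
    cell_size: float
    crs: LocalEquirectangular
    year: int
    group_map: Mapping[int, Group] = field(default_factory=lambda: dict(DEFAULT_GROUP_MAP))

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def ny(self) -> int:
        return self.classes.shape[0]

    @property
    def nx(self) -> int:
        return self.classes.shape[1]

    def group_of(self, code: int) -> Group:
        return self.group_map.get(int(code), Group.OTHER)

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        ix = int(math.floor((x - self.x0) / self.cell_size))
        iy = int(math.floor((y - self.y0) / self.cell_size))
        if not (0 <= ix < self.nx and 0 <= iy < self.ny):
            raise LandCoverError(f"point ({x:.1f}, {y:.1f}) m outside raster extent")
        return ix, iy

    def sample(self, lon: float, lat: float) -> int:
        """Class code of the single cell containing the point."""
        x, y = self.crs.to_xy(lon, lat)
        ix, iy = self.cell_index(float(x), float(y))
        return int(self.classes[iy, ix])

    # -- text serialization (ESRI ASCII grid; row order top-down on disk) ---
    def to_ascii(self, path: str | Path) -> None:
        header = (
            f"ncols {self.nx}\nnrows {self.ny}\n"
            f"xllcorner {self.x0}\nyllcorner {self.y0}\n"
            f"cellsize {self.cell_size}\nNODATA_value -9999\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.classes[::-1], fmt="%d")

    @classmethod
    def from_ascii(
        cls,
        path: str | Path,
        crs: LocalEquirectangular,
        year: int,
        group_map: Mapping[int, Group] | None = None,
    ) -> "LandCoverGrid":
        with open(path) as fh:
            header = {}
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            data = np.loadtxt(fh, dtype=int)
        data = np.atleast_2d(data)[::-1]
        return cls(
            classes=data,
            x0=header["xllcorner"],
            y0=header["yllcorner"],
            cell_size=header["cellsize"],
            crs=crs,
            year=year,
            group_map=dict(group_map or DEFAULT_GROUP_MAP),
        )


def vintage_for_year(year: int, vintages: list[int]) -> int:
    """Raster vintage serving a given fire year.

    Vintages are released every few years; a fire in year Y uses the most
    recent vintage not after Y (e.g. the 2013 release covers 2013-2015 when
    the next release is 2016).  Years before the first vintage fall back to
    the earliest one.
    """
    if not vintages:
        raise ValueError("vintages must be a non-empty list of years")
    vs = sorted(vintages)
    eligible = [v for v in vs if v <= year]
    return eligible[-1] if eligible else vs[0]


def dominant_land_cover(
    lon: float, lat: float, area_acres: float, lc: LandCoverGrid
) -> tuple[int, Group]:
    """Dominant class/group in a square footprint of the record's area.

    The footprint is an axis-aligned square in the raster CRS, side
    ``sqrt(area)``, centered on the record point.  The modal class among
    cells whose centers fall inside the square wins; if the square is too
    small to contain any cell center, the cell containing the point is used.
    Modal ties break toward non-AGRICULTURE groups first (conservative
    against over-flagging agricultural burns), then the lowest class code.
    """
    x, y = lc.crs.to_xy(lon, lat)
    x, y = float(x), float(y)
    lc.cell_index(x, y)  # raises if the point itself is off the raster
    side = math.sqrt(max(area_acres, 0.0) * ACRE_M2)
    half = side / 2.0
    c = lc.cell_size
    # cell centers at x0 + (i + 0.5) c inside [x - half, x + half]
    i_min = math.ceil((x - half - lc.x0) / c - 0.5)
    i_max = math.floor((x + half - lc.x0) / c - 0.5)
    j_min = math.ceil((y - half - lc.y0) / c - 0.5)
    j_max = math.floor((y + half - lc.y0) / c - 0.5)
    i_min, i_max = max(i_min, 0), min(i_max, lc.nx - 1)
    j_min, j_max = max(j_min, 0), min(j_max, lc.ny - 1)
    if i_min > i_max or j_min > j_max:
        ix, iy = lc.cell_index(x, y)
        code = int(lc.classes[iy, ix])
        return code, lc.group_of(code)
    window = lc.classes[j_min : j_max + 1, i_min : i_max + 1]
    codes, counts = np.unique(window, return_counts=True)
    top = counts.max()
    tied = [int(code) for code, n in zip(codes, counts) if n == top]
    tied.sort(key=lambda code: (lc.group_of(code) is Group.AGRICULTURE, code))
    code = tied[0]
    return code, lc.group_of(code)
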