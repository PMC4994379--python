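"""Minimal raster grid model shared by every stage of the pipeline.

All rasters live on one local Cartesian grid: 0-based (row, col) indexing, a
fixed pixel size in metres (default 250 m, i.e. 6.25 ha per pixel) and an
affine origin (x0, y0) of the upper-left corner. No map projection is
modelled; a real georeferenced product is a drop-in replacement as long as
its grid is shared by all inputs.

Rasters are serialised as TIFF with the grid metadata stored as a JSON
document in the image-description tag, so every intermediate artifact can be
re-loaded in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: pixel edge length used throughout, metres
DEFAULT_PIXEL_SIZE_M = 250.0

#: hectares covered by one 250 m pixel
PIXEL_AREA_HA = 6.25

#: months of the fire season handled by the burn-scar chain
FIRE_SEASON_MONTHS = (6, 7, 8, 9, 10)

MONTH_NAMES = {0: "none", 6: "Jun", 7: "Jul", 8: "Aug", 9: "Sep", 10: "Oct"}

# 4-connectivity structuring element for every connected-component operation
STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class Raster:
    """A single- or multi-band raster on the shared grid.

    ``data`` is (rows, cols) or (rows, cols, bands); ``origin`` is the
    (x, y) map coordinate of the upper-left corner.
    """

    data: np.ndarray
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or 3-D (rows, cols[, bands])")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    @property
    def pixel_area_ha(self) -> float:
        return (self.pixel_size_m / 100.0) ** 2

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and abs(self.pixel_size_m - other.pixel_size_m) < 1e-9
            and abs(self.origin[0] - other.origin[0]) < 1e-6
            and abs(self.origin[1] - other.origin[1]) < 1e-6
        )

    def with_data(self, data: np.ndarray) -> "Raster":
        return replace(self, data=data)

    # --- I/O -----------------------------------------------------------
    def write(self, path) -> None:
        meta = {
            "pixel_size_m": self.pixel_size_m,
            "origin": list(self.origin),
            "dtype": str(self.data.dtype),
        }
        tifffile.imwrite(
            path, self.data, description=json.dumps(meta), photometric="minisblack"
        )

    @classmethod
    def read(cls, path) -> "Raster":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        pixel_size, origin = DEFAULT_PIXEL_SIZE_M, (0.0, 0.0)
        if desc:
            try:
                meta = json.loads(desc)
                pixel_size = float(meta.get("pixel_size_m", pixel_size))
                origin = tuple(meta.get("origin", origin))
            except (ValueError, TypeError):
                pass
        return cls(data=data, pixel_size_m=pixel_size, origin=origin)


def check_shared_grid(*rasters: Raster) -> None:
    """Raise if the rasters do not share one grid (shape, pixel, origin)."""
    first = rasters[0]
    for r in rasters[1:]:
        if not first.same_grid(r):
            raise ValueError(
                f"rasters on different grids: {first.shape}@{first.origin} vs "
                f"{r.shape}@{r.origin}"
            )


@dataclass
class BurnScarMap:
    """Cumulative burn mask with the first-burn month per pixel.

    ``month`` holds 0 for never-burned pixels and the calendar month
    (6..10) of the first detection otherwise; a pixel, once burned, stays
    burned — repeated burns of the same pixel are not represented.
    """

    month: np.ndarray
    pixel_size_m: float = DEFAULT_PIXEL_SIZE_M
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.month = np.asarray(self.month, dtype=np.uint8)
        bad = set(np.unique(self.month)) - ({0} | set(FIRE_SEASON_MONTHS))
        if bad:
            raise ValueError(f"invalid first-burn month codes: {sorted(bad)}")

    @property
    def burned(self) -> np.ndarray:
        return self.month > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.month.shape

    @property
    def pixel_area_ha(self) -> float:
        return (self.pixel_size_m / 100.0) ** 2

    def burned_area_ha(self) -> float:
        return float(self.burned.sum()) * self.pixel_area_ha

    def as_raster(self) -> Raster:
        return Raster(self.month, self.pixel_size_m, self.origin)

    def write(self, path) -> None:
        # band 0: 0/1 burned flag, band 1: first-burn month code
        stack = np.stack([self.burned.astype(np.uint8), self.month], axis=-1)
        Raster(stack, self.pixel_size_m, self.origin).write(path)

    @classmethod
    def read(cls, path) -> "BurnScarMap":
        r = Raster.read(path)
        month = r.data[..., 1] if r.data.ndim == 3 else r.data
        return cls(month=month, pixel_size_m=r.pixel_size_m, origin=r.origin)
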