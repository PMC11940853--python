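"""Core containers and the class legend shared by every stage.

The package works in a single projected metric frame: coordinates are
meters, the origin sits at the lower-left corner of the region, and rasters
store row 0 at the top (north). No geodesy is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA: int = 255

# Land-use/cover class codes. Abbreviations follow the regional Portuguese
# shorthand used for metric column names (AGPE = small-scale agriculture,
# AGLE = large-scale agriculture, PL = herbaceous pasture, PS = shrub
# pasture, VSI/VSA = initial/advanced secondary vegetation, HID =
# hydrography, FLO = forest, NF = non-forest, ALTO = high potential of
# occurrence of acai palms).
LANDCOVER_CODES: dict[str, int] = {
    "small_scale_ag": 1,
    "large_scale_ag": 2,
    "herb_pasture": 3,
    "shrub_pasture": 4,
    "init_sec_veg": 5,
    "adv_sec_veg": 6,
    "hydrography": 7,
    "forest": 8,
    "non_forest": 9,
}
HIGH_ACAI_CODE: int = 10  # only present in the unified product

CLASS_ABBREV: dict[int, str] = {
    1: "AGPE",
    2: "AGLE",
    3: "PL",
    4: "PS",
    5: "VSI",
    6: "VSA",
    7: "HID",
    8: "FLO",
    9: "NF",
    10: "ALTO",
}

#: Hydro-topographic zone codes (distance-to-river bands standing in for a
#: full hydro-topographic mapping).
ZONE_CODES: dict[str, int] = {
    "lowland": 1,
    "transition": 2,
    "slope": 3,
    "upland": 4,
}

#: Acai-potential codes, ordered from absent to high.
POTENTIAL_CODES: dict[str, int] = {
    "absent": 0,
    "low": 1,
    "moderate": 2,
    "high": 3,
}

#: Fixed PLU class order; ties everywhere break toward the earlier entry.
PLU_CLASSES: tuple[str, ...] = ("PLU1", "PLU2", "PLU3", "PLU4", "PLU5")

#: Vegetated land-cover codes (primary forest plus both secondary stages).
VEGETATED_CODES: frozenset[int] = frozenset(
    {LANDCOVER_CODES["forest"], LANDCOVER_CODES["init_sec_veg"], LANDCOVER_CODES["adv_sec_veg"]}
)


class LegendError(ValueError):
    """A raster holds a code that the legend does not declare."""


@dataclass
class Raster:
    """Single-band categorical raster on a regular metric grid.

    Parameters
    ----------
    data:
        2-D integer array, row 0 = north.
    origin:
        ``(x, y)`` of the lower-left corner in meters.
    resolution_m:
        Pixel side length in meters.
    nodata:
        Code marking unobserved pixels.
    """

    data: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    resolution_m: float = 10.0
    nodata: int = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.resolution_m <= 0:
            raise ValueError("resolution must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def width_m(self) -> float:
        return self.data.shape[1] * self.resolution_m

    @property
    def height_m(self) -> float:
        return self.data.shape[0] * self.resolution_m

    def same_frame(self, other: "Raster") -> bool:
        """True when the two rasters are pixel-for-pixel co-registered."""
        return (
            self.shape == other.shape
            and self.origin == other.origin
            and self.resolution_m == other.resolution_m
        )

    def require_same_frame(self, other: "Raster") -> None:
        if not self.same_frame(other):
            raise ValueError(
                f"raster frames differ: shape {self.shape} vs {other.shape}, "
                f"origin {self.origin} vs {other.origin}, "
                f"resolution {self.resolution_m} vs {other.resolution_m}"
            )

    def validate_codes(self, allowed: set[int] | frozenset[int]) -> None:
        """Raise :class:`LegendError` naming a pixel with an unknown code."""
        mask = ~np.isin(self.data, list(allowed) + [self.nodata])
        if mask.any():
            r, c = np.argwhere(mask)[0]
            raise LegendError(
                f"unknown class code {int(self.data[r, c])} at pixel (row={r}, col={c})"
            )

    def pixel_area_ha(self) -> float:
        return self.resolution_m**2 / 10_000.0


@dataclass
class Legend:
    """Class-code legend, externally serializable as YAML."""

    name: str
    codes: dict[str, int]
    nodata: int = NODATA
    version: str = "1"

    @property
    def by_code(self) -> dict[int, str]:
        return {v: k for k, v in self.codes.items()}

    def allowed_codes(self) -> frozenset[int]:
        return frozenset(self.codes.values())


def landcover_legend() -> Legend:
    return Legend(name="landcover", codes=dict(LANDCOVER_CODES))


def unified_legend() -> Legend:
    codes = dict(LANDCOVER_CODES)
    codes["high_acai_potential"] = HIGH_ACAI_CODE
    return Legend(name="unified", codes=codes)


def hydrotopo_legend() -> Legend:
    return Legend(name="hydrotopo", codes=dict(ZONE_CODES))


@dataclass
class VectorLayer:
    """A bag of shapely geometries with optional per-feature properties."""

    geometries: list = field(default_factory=list)
    properties: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.properties:
            self.properties = [{} for _ in self.geometries]
        if len(self.properties) != len(self.geometries):
            raise ValueError("properties and geometries length mismatch")

    def __len__(self) -> int:
        return len(self.geometries)

    def __iter__(self):
        return iter(zip(self.geometries, self.properties))
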