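"""Rule-based indicator of potential occurrence of native acai palms.

Acai (*Euterpe oleracea*) anchors the riverine extractive economy of the
eastern Amazon: dense natural stands grow under forest cover on seasonally
flooded lowlands and on the transition belts between floodplain and slope.
The indicator combines the categorical land-cover map with a four-zone
hydro-topographic map:

* **high** — primary or secondary forest cover on lowland or transition;
* **moderate** — primary forest on slopes;
* **low** — secondary vegetation and/or forest on upland (and, by the
  package's default reading, secondary vegetation on slopes — the published
  rules name only "forest cover" there);
* **absent** — any pixel without primary forest or secondary vegetation.

The high-potential class is then folded back into the land-cover product,
forming the unified database that feeds the landscape metrics.
"""

from __future__ import annotations

import numpy as np

from .core import (
    HIGH_ACAI_CODE,
    LANDCOVER_CODES,
    POTENTIAL_CODES,
    VEGETATED_CODES,
    ZONE_CODES,
    Raster,
)

_SECONDARY = (LANDCOVER_CODES["init_sec_veg"], LANDCOVER_CODES["adv_sec_veg"])


def classify_acai_potential(
    landcover: Raster,
    hydrotopo: Raster,
    *,
    secondary_on_slope: str = "low",
) -> Raster:
    """Assign one acai-potential code to every co-registered pixel.

    Parameters
    ----------
    landcover, hydrotopo:
        Co-registered categorical rasters (same frame).
    secondary_on_slope:
        Potential assigned to secondary vegetation on slope zones, which the
        published rules leave unstated. One of ``"low"`` (default),
        ``"moderate"`` or ``"absent"``.
    """
    landcover.require_same_frame(hydrotopo)
    landcover.validate_codes(frozenset(LANDCOVER_CODES.values()))
    hydrotopo.validate_codes(frozenset(ZONE_CODES.values()))
    if secondary_on_slope not in POTENTIAL_CODES or secondary_on_slope == "high":
        raise ValueError(f"invalid secondary_on_slope: {secondary_on_slope!r}")

    lc, zone = landcover.data, hydrotopo.data
    vegetated = np.isin(lc, list(VEGETATED_CODES))
    secondary = np.isin(lc, _SECONDARY)
    forest = lc == LANDCOVER_CODES["forest"]
    lowland_or_transition = np.isin(zone, (ZONE_CODES["lowland"], ZONE_CODES["transition"]))
    slope = zone == ZONE_CODES["slope"]
    upland = zone == ZONE_CODES["upland"]

    out = np.full(lc.shape, POTENTIAL_CODES["absent"], dtype=np.uint8)
    out[vegetated & upland] = POTENTIAL_CODES["low"]
    out[secondary & slope] = POTENTIAL_CODES[secondary_on_slope]
    out[forest & slope] = POTENTIAL_CODES["moderate"]
    out[vegetated & lowland_or_transition] = POTENTIAL_CODES["high"]

    nodata_mask = (lc == landcover.nodata) | (zone == hydrotopo.nodata)
    out[nodata_mask] = landcover.nodata
    return Raster(out, landcover.origin, landcover.resolution_m, landcover.nodata)


def integrate_landcover(landcover: Raster, potential: Raster) -> Raster:
    """Fold the high-potential class into the land-cover map.

    Pixels flagged ``high`` are recoded to ``high_acai_potential``; every
    other pixel keeps its land-cover class, so pixel count is conserved and
    non-vegetation classes pass through untouched.
    """
    landcover.require_same_frame(potential)
    out = landcover.data.copy()
    out[potential.data == POTENTIAL_CODES["high"]] = HIGH_ACAI_CODE
    return Raster(out, landcover.origin, landcover.resolution_m, landcover.nodata)
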