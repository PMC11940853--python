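"""Extract the per-cell feature table from the exported region.

Runs the acai-potential rules, unifies the land cover, builds the 2 x 2 km
grid and computes every landscape and context metric per cell. The full
table goes to scratch/ (it is bulky); the column inventory and a few
illustrative named metrics are printed.
"""

import json
from pathlib import Path

import plumap.io as pio
from plumap.core import hydrotopo_legend, landcover_legend, unified_legend
from plumap.metrics import feature_schema
from plumap.pipeline import extract_features

ROOT = Path(__file__).resolve().parents[1]
REGION = ROOT / "scratch" / "region"


def main() -> None:
    if not (REGION / "landcover.asc").exists():
        raise SystemExit("run analysis/01_simulate_region.py first")
    landcover = pio.read_raster(REGION / "landcover.asc", landcover_legend())
    hydrotopo = pio.read_raster(REGION / "hydrotopo.asc", hydrotopo_legend())
    rivers = pio.read_geojson(REGION / "rivers.geojson")
    roads = pio.read_geojson(REGION / "roads.geojson")
    establishments = pio.read_geojson(REGION / "establishments.geojson")
    features, grid, unmapped = extract_features(
        landcover, hydrotopo, rivers, roads, establishments
    )
    features.to_csv(ROOT / "scratch" / "features.csv", float_format="%.6f")
    with open(ROOT / "scratch" / "features_schema.json", "w") as fh:
        json.dump(feature_schema(unified_legend()), fh, indent=1)
    print(f"{features.shape[0]} cells x {features.shape[1]} metrics "
          f"({len(unmapped)} cells unmapped)")
    named = ["CA_VSA", "LSI_PL", "PD_AGLE", "AWMPFD_AGLE", "MPS_AGPE",
             "TABO_ALTO", "HID_min", "P_HID", "IJI_HID"]
    print("named metrics, first four cells:")
    print(features[named].head(4).round(3).to_string())


if __name__ == "__main__":
    main()
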