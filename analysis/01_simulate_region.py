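"""Generate the synthetic study region and export it for the later steps.

A 30 x 30 km region (225 cells of 2 x 2 km at 10 m resolution) is generated
with the five PLU archetypes mixed in proportion to the labeled-sample
design. Heavy rasters go to scratch/region/; a small composition summary
goes to results/.
"""

import json
import sys
from pathlib import Path

from plumap.evaluation import summarize_plu
from plumap.study import study_region_config
from plumap.synthetic import export_region, generate_region

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    region = generate_region(study_region_config(SEED))
    paths = export_region(region, ROOT / "scratch" / "region")
    summary = summarize_plu(region.truth_labels)
    print(f"generated {len(region.grid)} cells ({region.config.extent_m[0] / 1e3:.0f} km square)")
    print(f"rivers: {len(region.rivers)}, roads: {len(region.roads)}, "
          f"establishments: {len(region.establishments)}")
    for plu in sorted(summary.counts):
        print(f"  {plu}: {summary.counts[plu]} cells ({summary.shares_pct[plu]:.1f}%)")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    with open(out / "region_composition.json", "w") as fh:
        json.dump(
            {"seed": SEED, "cells": summary.counts, "shares_pct": summary.shares_pct},
            fh,
            indent=1,
        )
    print(f"region exported to {paths['landcover'].parent}")


if __name__ == "__main__":
    main()
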