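"""Summarize PLU shares: the published study region and our synthetic map.

Recomputes the percentage shares of the mapped study region (Mocajuba +
Cametá, 2021; 1,085 mapped cells) from its per-PLU cell counts, and puts
the synthetic map's shares beside them. The two columns are expected to
differ: the synthetic mix is proportional to the sampling design, not to
the real region.
"""

import json
from pathlib import Path

import pandas as pd

from plumap.evaluation import summarize_plu
from plumap.study import CELLS_GENERATED, STUDY_REGION_COUNTS

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = summarize_plu(STUDY_REGION_COUNTS)
    rows = {
        plu: {"study_cells": STUDY_REGION_COUNTS[plu],
              "study_share_pct": round(study.shares_pct[plu], 1)}
        for plu in sorted(STUDY_REGION_COUNTS)
    }
    map_path = ROOT / "results" / "map_assessment.json"
    if map_path.exists():
        counts = json.loads(map_path.read_text())["map_counts"]
        synth = summarize_plu(counts)
        for plu in rows:
            rows[plu]["synthetic_cells"] = counts.get(plu, 0)
            rows[plu]["synthetic_share_pct"] = round(synth.shares_pct.get(plu, 0.0), 1)
    frame = pd.DataFrame(rows).T
    frame.index.name = "plu"
    print(f"study region: {sum(CELLS_GENERATED.values())} cells generated, "
          f"{study.mapped_total} mapped")
    print(f"peasant PLUs (PLU1-3): {study.peasant_share_pct:.1f}% of mapped cells; "
          f"capitalist PLUs (PLU4-5): {study.capitalist_share_pct:.1f}%")
    print(frame.to_string())
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    frame.to_csv(out / "plu_shares.csv")


if __name__ == "__main__":
    main()
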