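#!/usr/bin/env python
"""Composition-only accounting on the published district tables.

Carbon stocks are area × density, so the printed class compositions are a
sufficient input: this step recomputes the carbon stock of the 2014 map
and both 2030 scenarios, the scenario change arithmetic for services and
class areas, and the suitability-structure totals, and writes them under
results/.  These are the same quantities scripts/acceptance.py reports.
"""

from pathlib import Path

import pandas as pd

from luces.pipeline import compare_scenarios
from luces.services import DEFAULT_CARBON_DENSITY, carbon_stock_from_areas
from luces.study import COMPOSITIONS, compositions, es_totals, suitability_structure

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cs = pd.Series({
        name: carbon_stock_from_areas(comp, DEFAULT_CARBON_DENSITY) / 1e4
        for name, comp in COMPOSITIONS.items()
    }, name="carbon_stock_1e4t")
    cs.to_csv(OUT / "published_carbon_stocks.csv")
    print("carbon stocks (10⁴ t):")
    print(cs.to_string(float_format=lambda v: f"{v:.2f}"))

    es_changes = compare_scenarios(es_totals(), base="2014")
    es_changes.to_csv(OUT / "published_es_changes.csv", index=False)
    area_changes = compare_scenarios(compositions(), base="2014")
    area_changes.to_csv(OUT / "published_area_changes.csv", index=False)
    print("\nservice changes vs 2014:")
    print(es_changes[["service", "scenario", "change", "pct_change"]].to_string(
        index=False, float_format=lambda v: f"{v:.4f}"))

    suit = suitability_structure()
    suit.loc["column_total"] = suit.sum(axis=0)
    suit.to_csv(OUT / "published_suitability_structure.csv")
    cl = suit.loc["appropriate", "CL"] + suit.loc["relatively_appropriate", "CL"]
    print(f"\ncropland suitable total: {cl:.2f} km²; "
          f"column totals {suit.loc['column_total'].unique().round(2)}")


if __name__ == "__main__":
    main()
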