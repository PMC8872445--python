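#!/usr/bin/env python
"""Ecosystem-service assessment and scenario comparison.

Computes water yield (Budyko), the soil budget (USLE/RUSLE + routed
sediment retention) and carbon stocks for the base map and both scenario
maps, then tabulates absolute and percent changes against the base — the
synthetic-district analogue of comparing a prediction and an optimization
against the present situation.
"""

from pathlib import Path

import pandas as pd

from luces.grid import RasterStack, read_grid
from luces.pipeline import compare_scenarios
from luces.services import assess_all

DISTRICT = Path(__file__).resolve().parent.parent / "results" / "district"
OUT = Path(__file__).resolve().parent.parent / "results"

LAYERS = ("dem", "precipitation", "et0", "awc", "erosivity", "erodibility")


def main() -> None:
    stack = RasterStack(
        {name: read_grid(DISTRICT / f"{name}.tif", "continuous") for name in LAYERS}
    )
    grids = {"base": read_grid(sorted(DISTRICT.glob("lucc_t*.tif"))[-1], "landcover")}
    for name in ("scenario_1", "scenario_2"):
        path = OUT / f"{name}.tif"
        if path.exists():
            grids[name] = read_grid(path, "landcover")
    if len(grids) < 2:
        raise SystemExit("run 04_ca_markov.py / 05_optimize_structure.py first")

    totals = pd.DataFrame(
        {name: assess_all(stack, grid).totals for name, grid in grids.items()}
    )
    totals.to_csv(OUT / "es_totals.csv")
    print("service totals:")
    print(totals.to_string(float_format=lambda v: f"{v:.6g}"))

    changes = compare_scenarios(totals, base="base")
    changes.to_csv(OUT / "es_changes.csv", index=False)
    print("\nchanges vs base:")
    print(changes[["service", "scenario", "change", "pct_change"]].to_string(
        index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
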