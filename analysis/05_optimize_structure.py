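#!/usr/bin/env python
"""Grey-linear structure optimization and suitability-priority allocation.

Fits GM(1,1) models to each class's simulated area trajectory, bounds the
2030-style structure LP by the grey forecasts (±10 %), maximizes an
equal-weight ecology + economy objective, and allocates the optimized
demand by suitability priority to produce the optimized scenario map.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from luces.grid import class_areas, read_grid, write_grid
from luces.optimize import StructureLP, grey_fit, priority_allocate, solve_structure
from luces.suitability import build_atlas

SEED = 7
DISTRICT = Path(__file__).resolve().parent.parent / "results" / "district"
OUT = Path(__file__).resolve().parent.parent / "results"

# benefit coefficients per km² (documented placeholders, config in real use)
ECO = {"FL": 1.0, "SL": 0.8, "GL": 0.6, "WB": 0.9, "CL": 0.3, "OC": 0.4,
       "WL": 0.2, "BL": 0.0, "BUL": 0.0}
ECON = {"BUL": 1.0, "OC": 0.6, "CL": 0.5, "FL": 0.3, "SL": 0.2, "GL": 0.2,
        "WB": 0.3, "WL": 0.0, "BL": 0.0}


def main() -> None:
    series = [read_grid(p, "landcover") for p in sorted(DISTRICT.glob("lucc_t*.tif"))]
    if len(series) < 3:
        raise SystemExit("run 01_simulate_district.py first")
    base = series[-1]
    areas = class_areas(base).set_index("class_label")["area_km2"]

    trajectories = pd.DataFrame(
        {f"t{i}": class_areas(g).set_index("class_label")["area_km2"]
         for i, g in enumerate(series)}
    )
    lower, upper = {}, {}
    for label, row in trajectories.iterrows():
        obs = row.to_numpy()
        if len(obs) >= 4 and (obs > 0).all():
            target = float(grey_fit(obs).forecast(1)[0])
        else:  # short series: extrapolate the last interval linearly
            target = max(float(obs[-1] + (obs[-1] - obs[-2])), 0.0)
        lower[label] = max(target * 0.9, 0.0)
        upper[label] = target * 1.1 if target > 0 else areas[label]
    print("grey/linear forecast bounds (km²):")
    print(pd.DataFrame({"lower": lower, "upper": upper}).to_string(
        float_format=lambda v: f"{v:.4f}"))

    lp = StructureLP(
        total_area=float(areas.sum()),
        eco_benefit=ECO, econ_benefit=ECON,
        lower=lower, upper=upper,
    )
    demand = solve_structure(lp)
    print("optimized structure (km²):",
          np.round(demand.areas, 4), f"total {demand.total:.4f}")

    layers = {
        "slope": read_grid(DISTRICT / "slope.tif", "continuous").values,
        "elevation": read_grid(DISTRICT / "dem.tif", "continuous").values,
        "ph": read_grid(DISTRICT / "ph.tif", "continuous").values,
    }
    atlas = build_atlas(layers, cell_size=base.cell_size)
    scenario_2 = priority_allocate(base, demand, atlas, seed=SEED)
    write_grid(OUT / "scenario_2.tif", scenario_2)

    comparison = pd.DataFrame({
        "base_km2": areas,
        "scenario_2_km2": class_areas(scenario_2).set_index("class_label")["area_km2"],
    })
    comparison.to_csv(OUT / "scenario_2_composition.csv")
    print(comparison.to_string(float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
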