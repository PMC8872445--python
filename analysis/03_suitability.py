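#!/usr/bin/env python
"""Land-suitability evaluation of the synthetic district.

Grades slope, elevation and soil pH per land-use class, aggregates them
with equal AHP weights (a worked expert matrix is solved and checked for
consistency first), writes per-class grade rasters, the five-digit
composite-code raster and the suitability area table, and prints the
share of the district suitable for cropland — small, as expected for a
mountainous district with a steep-slope farming ban.
"""

from pathlib import Path

import numpy as np

from luces.grid import Raster, read_grid, write_grid
from luces.suitability import (
    ahp_weights,
    build_atlas,
    encode_composite,
    suitability_area_table,
)

DISTRICT = Path(__file__).resolve().parent.parent / "results" / "district"
OUT = Path(__file__).resolve().parent.parent / "results" / "suitability"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    slope = read_grid(DISTRICT / "slope.tif", "continuous")
    dem = read_grid(DISTRICT / "dem.tif", "continuous")
    ph = read_grid(DISTRICT / "ph.tif", "continuous")

    # a consistent three-criterion comparison: slope twice as important as
    # elevation, four times as important as pH
    expert = np.array([[1, 2, 4], [1 / 2, 1, 2], [1 / 4, 1 / 2, 1]])
    res = ahp_weights(expert)
    print(f"AHP weights {np.round(res.weights, 4)}, CR={res.consistency_ratio:.4f} "
          f"({'accepted' if res.consistent else 'REJECTED'})")

    layers = {"slope": slope.values, "elevation": dem.values, "ph": ph.values}
    weights = {label: res.weights for label in ("CL", "OC", "FL", "GL", "SL")}
    atlas = build_atlas(layers, cell_size=slope.cell_size, weights=weights)

    for label, grade in atlas.grades.items():
        write_grid(OUT / f"grade_{label}.tif", Raster(grade, slope.cell_size))
    write_grid(OUT / "composite_code.tif",
               Raster(encode_composite(atlas), slope.cell_size))

    table = suitability_area_table(atlas)
    table.to_csv(OUT / "suitability_structure.csv")
    print(table.to_string(float_format=lambda v: f"{v:.4f}"))
    total = table.loc[["appropriate", "relatively_appropriate", "inappropriate"]].sum()
    cl_share = table.loc["suitable_total", "CL"] / total["CL"] * 100
    print(f"share of district suitable for cropland: {cl_share:.1f}%")


if __name__ == "__main__":
    main()
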