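#!/usr/bin/env python
"""Generate the synthetic mountainous district used by the later steps.

Writes the continuous raster stack (DEM, slope, climate, soils) and a
three-date land-cover series driven by a known diagonal-dominant Markov
matrix to results/district/, and prints the terrain stratum shares and the
initial class composition.
"""

from pathlib import Path

import numpy as np

from luces.grid import class_areas, write_grid
from luces.synthetic import (
    STRATUM_SHARES,
    SyntheticConfig,
    elevation_strata,
    make_initial_lucc,
    make_terrain,
    simulate_series,
)

SEED = 7
SHAPE = (100, 100)
OUT = Path(__file__).resolve().parent.parent / "results" / "district"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(shape=SHAPE, seed=SEED)
    stack = make_terrain(cfg)
    for name in stack.names():
        write_grid(OUT / f"{name}.tif", stack[name])

    strata = elevation_strata(stack["dem"].values)
    shares = np.bincount(strata.ravel(), minlength=3) / strata.size
    print("terrain stratum shares (plain/hill/mountain):",
          np.round(shares, 3), "targets:", STRATUM_SHARES)

    initial = make_initial_lucc(stack, cfg.class_affinity, seed=SEED)
    series = simulate_series(initial, cfg.true_transition, 2, seed=SEED)
    for i, grid in enumerate(series):
        write_grid(OUT / f"lucc_t{i}.tif", grid)

    table = class_areas(series[0])
    table.to_csv(OUT / "initial_composition.csv", index=False)
    print("initial composition (km²):")
    print(table.to_string(index=False))
    print(f"wrote stack + {len(series)} land-cover dates to {OUT}")


if __name__ == "__main__":
    main()
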