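#!/usr/bin/env python
"""Transfer matrices and landscape-pattern metrics on the simulated series.

Cross-tabulates consecutive land-cover dates into area/probability matrices
(also exported in the circos flow-table format), computes NP/PD/MPS/
COHESION per class and date, and prints the persistence share of each
interval — on the synthetic district most land stays put, as in any real
series dominated by stable forest and shrubland.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from luces.grid import read_grid
from luces.metrics import compute_metrics
from luces.transitions import cross_tabulate, export_transfer_table

DISTRICT = Path(__file__).resolve().parent.parent / "results" / "district"
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dates = sorted(DISTRICT.glob("lucc_t*.tif"))
    if not dates:
        raise SystemExit("run 01_simulate_district.py first")
    series = [read_grid(p, "landcover") for p in dates]

    for i, (a, b) in enumerate(zip(series, series[1:])):
        m = cross_tabulate(a, b, f"t{i}", f"t{i+1}")
        m.to_frame("areas").to_csv(OUT / f"transition_areas_{i}.csv")
        m.to_frame("probabilities").to_csv(OUT / f"transition_probabilities_{i}.csv")
        export_transfer_table(m, OUT / f"transfer_table_{i}.tsv")
        persist = np.trace(m.areas) / m.areas.sum()
        print(f"interval t{i}->t{i+1}: persistence share {persist:.3f}")

    frames = []
    for i, grid in enumerate(series):
        table = compute_metrics(grid)
        table.insert(0, "date", f"t{i}")
        frames.append(table)
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(OUT / "landscape_metrics.csv", index=False)
    print(metrics.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


if __name__ == "__main__":
    main()
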