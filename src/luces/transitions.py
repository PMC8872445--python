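"""Land-cover transfer matrices between two dates.

Cross-tabulates a pair of aligned categorical grids into a 9×9 area matrix
(km² converted from class i at date 1 to class j at date 2, diagonal =
persistence) and its row-stochastic probability form.  Cells that are
nodata in either grid are excluded entirely, which keeps the conservation
identities exact: row sums equal date-1 class areas, column sums equal
date-2 class areas (on the common valid mask).

The area matrix can be exported as the tab-delimited flow table consumed by
the circos/tableviewer convention (labels in fixed legend order).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import CLASS_CODES, LEGEND, LandCoverGrid, check_aligned


@dataclass
class TransitionMatrix:
    """Areas (km²) and row-stochastic probabilities between two dates."""

    areas: np.ndarray
    cell_size: float
    date_from: str = "t0"
    date_to: str = "t1"
    labels: tuple[str, ...] = field(default_factory=lambda: tuple(LEGEND.values()))

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.labels)
        if self.areas.shape != (n, n):
            raise ValueError(f"areas must be {n}×{n}, got {self.areas.shape}")
        if (self.areas < 0).any():
            raise ValueError("transition areas must be nonnegative")

    @property
    def probabilities(self) -> np.ndarray:
        return to_probabilities(self.areas)

    def to_frame(self, kind: str = "areas") -> pd.DataFrame:
        data = self.areas if kind == "areas" else self.probabilities
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


def cross_tabulate(
    grid_a: LandCoverGrid,
    grid_b: LandCoverGrid,
    date_from: str = "t0",
    date_to: str = "t1",
) -> TransitionMatrix:
    """Cross-tabulate two aligned land-cover grids into a transfer matrix."""
    check_aligned(grid_a, grid_b)
    valid = grid_a.valid_mask & grid_b.valid_mask
    a = grid_a.values[valid] - 1
    b = grid_b.values[valid] - 1
    n = len(CLASS_CODES)
    counts = np.bincount(a * n + b, minlength=n * n).reshape(n, n)
    areas = counts * grid_a.cell_area_km2
    return TransitionMatrix(areas, grid_a.cell_size, date_from, date_to)


def to_probabilities(areas: np.ndarray) -> np.ndarray:
    """Row-normalize an area matrix; all-zero rows take the identity
    convention (a class absent at date 1 persists)."""
    areas = np.asarray(areas, dtype=float)
    sums = areas.sum(axis=1, keepdims=True)
    probs = np.where(sums > 0, areas / np.where(sums > 0, sums, 1.0), 0.0)
    for i in np.flatnonzero(sums.ravel() == 0):
        probs[i, i] = 1.0
    return probs


def export_transfer_table(matrix: TransitionMatrix, path) -> None:
    """Write the areas matrix as a tab-delimited flow table: first row and
    first column carry the class labels, body is km²."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("labels\t" + "\t".join(matrix.labels) + "\n")
        for label, row in zip(matrix.labels, matrix.areas):
            fh.write(label + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def parse_transfer_table(path, cell_size: float = 30.0) -> TransitionMatrix:
    """Inverse of :func:`export_transfer_table`."""
    with open(path) as fh:
        header = fh.readline().split("\t")
        labels = tuple(s.strip() for s in header[1:])
        rows = []
        for line in fh:
            parts = line.split("\t")
            rows.append([float(v) for v in parts[1:]])
    return TransitionMatrix(np.array(rows), cell_size, labels=labels)
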