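"""Multi-criteria land-suitability evaluation with AHP weighting.

Workflow: each criterion raster (slope, aspect, elevation, soil pH, soil
loss, soil conservation, water yield, ...) is graded 4/3/2/1 by interval
lookup (4 = suitable, 3 = relatively suitable, 2 and 1 = unsuitable with
two severities); criterion weights come from an analytic-hierarchy-process
pairwise-comparison matrix solved by the principal eigenvector and accepted
when the consistency ratio CR < 0.1; per-class continuous scores are the
weighted mean of normalized grades, re-thresholded to a 4/3/2/1 grade
raster; the five class grades (cropland, orchard, forestland, grassland,
shrubland) are packed into a five-digit composite code per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridError

#: Saaty's random consistency index by matrix order.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24, 7: 1.32,
    8: 1.41, 9: 1.45, 10: 1.49, 11: 1.51, 12: 1.48, 13: 1.56,
    14: 1.57, 15: 1.59,
}

#: Classes that receive a suitability surface (legend labels, digit order of
#: the composite code: CL, OC, FL, GL, SL).
SUITABILITY_CLASSES = ("CL", "OC", "FL", "GL", "SL")

GRADES = (4, 3, 2, 1)

#: Normalized value of each grade for weighted aggregation.
GRADE_VALUE = {4: 1.0, 3: 2.0 / 3.0, 2: 1.0 / 3.0, 1: 0.0}

#: Continuous-score thresholds for grades 4 and 3 (config-overridable).
DEFAULT_THRESHOLDS = (0.75, 0.5)


class ConsistencyError(ValueError):
    """Raised for malformed pairwise-comparison matrices."""


@dataclass
class AHPResult:
    weights: np.ndarray
    lambda_max: float
    consistency_index: float
    consistency_ratio: float

    @property
    def consistent(self) -> bool:
        return self.consistency_ratio < 0.1


def ahp_weights(matrix: np.ndarray, reciprocal_tol: float = 1e-6) -> AHPResult:
    """Criterion weights from a positive reciprocal pairwise matrix.

    The weight vector is the principal right eigenvector normalized to sum
    one; CI = (λmax − n)/(n − 1) and CR = CI/RI(n) with Saaty's random
    index.  CR ≥ 0.1 is flagged via :attr:`AHPResult.consistent`, not fatal.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConsistencyError(f"pairwise matrix must be square, got {m.shape}")
    n = m.shape[0]
    if not 2 <= n <= 15:
        raise ConsistencyError(f"matrix order must be in [2, 15], got {n}")
    if (m <= 0).any():
        raise ConsistencyError("pairwise matrix must be strictly positive")
    if not np.allclose(m * m.T, 1.0, atol=reciprocal_tol):
        raise ConsistencyError("matrix is not reciprocal (m[i][j] != 1/m[j][i])")
    eigvals, eigvecs = np.linalg.eig(m)
    k = np.argmax(eigvals.real)
    lam = float(eigvals[k].real)
    w = np.abs(eigvecs[:, k].real)
    w = w / w.sum()
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX[n]
    cr = ci / ri if ri > 0 else 0.0
    # clip the tiny negative CI that floating-point eig can produce
    return AHPResult(w, lam, max(ci, 0.0), max(cr, 0.0))


def geometric_mean_matrix(matrices) -> np.ndarray:
    """Aggregate several experts' pairwise matrices by elementwise
    geometric mean (preserves reciprocity)."""
    arr = np.array([np.asarray(m, float) for m in matrices])
    return np.exp(np.log(arr).mean(axis=0))


def score_criterion(
    values: np.ndarray, breakpoints, grades
) -> np.ndarray:
    """Grade a criterion raster by interval membership.

    ``breakpoints`` are strictly increasing; ``grades`` has one entry per
    interval (len(breakpoints) + 1).  Intervals are half-open — a value
    exactly at a breakpoint falls in the upper interval.  NaN cells grade
    NaN.
    """
    breakpoints = np.asarray(breakpoints, dtype=float)
    if (np.diff(breakpoints) <= 0).any():
        raise ValueError("breakpoints must be strictly increasing")
    grades = np.asarray(grades, dtype=float)
    if len(grades) != len(breakpoints) + 1:
        raise ValueError(
            f"need {len(breakpoints) + 1} grades for {len(breakpoints)} breakpoints"
        )
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(breakpoints, values, side="right")
    out = grades[np.clip(idx, 0, len(grades) - 1)]
    return np.where(np.isnan(values), np.nan, out)


@dataclass
class SuitabilityAtlas:
    """Per-class continuous scores in [0,1] and 4/3/2/1 grade rasters."""

    scores: dict[str, np.ndarray] = field(default_factory=dict)
    grades: dict[str, np.ndarray] = field(default_factory=dict)
    cell_size: float = 30.0

    def add(self, label: str, score: np.ndarray, grade: np.ndarray) -> None:
        self.scores[label] = np.asarray(score, float)
        self.grades[label] = np.asarray(grade, float)

    @property
    def shape(self):
        return next(iter(self.scores.values())).shape


def composite_suitability(
    criterion_grades,
    weights,
    exclusion_mask: np.ndarray | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate criterion grade rasters into one class's (score, grade).

    Grades are normalized (4→1, 3→2/3, 2→1/3, 1→0) and combined as
    ``score = Σ w_k · norm_k``; the class grade is 4 where score ≥ t4,
    3 where score ≥ t3, otherwise 2 — deepened to 1 where some criterion
    sits at its worst grade, and forced to 1 wherever ``exclusion_mask``
    holds (an absolute constraint such as the steep-slope cropland ban).
    """
    weights = np.asarray(weights, dtype=float)
    criterion_grades = [np.asarray(g, float) for g in criterion_grades]
    if len(criterion_grades) != len(weights):
        raise ValueError(
            f"{len(weights)} weights for {len(criterion_grades)} criterion rasters"
        )
    shapes = {g.shape for g in criterion_grades}
    if len(shapes) != 1:
        raise GridError(f"criterion rasters are not aligned: shapes {shapes}")
    weights = weights / weights.sum()
    norm = np.zeros(criterion_grades[0].shape)
    for w, g in zip(weights, criterion_grades):
        norm = norm + w * (g - 1.0) / 3.0
    t4, t3 = thresholds
    worst = np.min(criterion_grades, axis=0)
    grade = np.where(
        norm >= t4, 4.0,
        np.where(norm >= t3, 3.0, np.where(worst <= 1.0, 1.0, 2.0)),
    )
    if exclusion_mask is not None:
        grade = np.where(exclusion_mask, 1.0, grade)
    nan = np.isnan(norm)
    return np.where(nan, np.nan, norm), np.where(nan, np.nan, grade)


def suitability_area_table(
    atlas: SuitabilityAtlas, valid_mask: np.ndarray | None = None
) -> pd.DataFrame:
    """Areas (km²) of appropriate (grade 4), relatively appropriate (3) and
    inappropriate (2 + 1) land per suitability class."""
    cell_km2 = atlas.cell_size**2 / 1e6
    rows = {}
    for label, grade in atlas.grades.items():
        g = grade if valid_mask is None else np.where(valid_mask, grade, np.nan)
        rows[label] = [
            np.nansum(g == 4) * cell_km2,
            np.nansum(g == 3) * cell_km2,
            (np.nansum(g == 2) + np.nansum(g == 1)) * cell_km2,
        ]
    table = pd.DataFrame(
        rows, index=["appropriate", "relatively_appropriate", "inappropriate"]
    )
    table.loc["suitable_total"] = table.loc["appropriate"] + table.loc["relatively_appropriate"]
    return table


def suitable_totals(table: pd.DataFrame) -> pd.Series:
    """Suitable area per class = appropriate + relatively appropriate."""
    return table.loc["appropriate"] + table.loc["relatively_appropriate"]


def encode_composite(atlas: SuitabilityAtlas) -> np.ndarray:
    """Pack the five class grades into a five-digit code per cell
    (digits left to right: CL, OC, FL, GL, SL)."""
    missing = [c for c in SUITABILITY_CLASSES if c not in atlas.grades]
    if missing:
        raise KeyError(f"atlas is missing grade rasters for {missing}")
    code = np.zeros(atlas.shape)
    for i, label in enumerate(SUITABILITY_CLASSES):
        code = code + atlas.grades[label] * 10 ** (4 - i)
    return code


def decode_composite(code: np.ndarray) -> dict[str, np.ndarray]:
    """Inverse of :func:`encode_composite`."""
    code = np.asarray(code)
    out = {}
    for i, label in enumerate(SUITABILITY_CLASSES):
        out[label] = (code // 10 ** (4 - i)) % 10
    return out


# ---------------------------------------------------------------------------
# Default criterion hierarchy (a documented reconstruction; user-overridable)
# ---------------------------------------------------------------------------

#: Breakpoints and grades per criterion and class.  Slope in degrees,
#: elevation in m, pH unitless, SLO t/ha, SC t/ha, WY m³/ha.  The cropland
#: steep-slope ban (slope ≥ 25°) is an absolute exclusion handled separately.
DEFAULT_CRITERIA: dict[str, dict[str, tuple]] = {
    "CL": {
        "slope": ((5.0, 15.0, 25.0), (4, 3, 2, 1)),
        "elevation": ((200.0, 500.0), (4, 3, 2)),
        "ph": ((5.5, 6.5, 7.5, 8.5), (2, 3, 4, 3, 2)),
        "slo": ((10.0,), (4, 2)),
        "wy": ((500.0, 1000.0, 1500.0), (2, 3, 4, 4)),
    },
    "OC": {
        "slope": ((5.0, 15.0, 25.0), (4, 4, 3, 2)),
        "elevation": ((200.0, 500.0), (4, 4, 2)),
        "ph": ((5.5, 6.5, 7.5, 8.5), (2, 4, 4, 3, 2)),
        "slo": ((10.0,), (4, 3)),
        "wy": ((500.0, 1000.0, 1500.0), (2, 3, 4, 4)),
    },
    "FL": {
        "slope": ((5.0, 15.0, 25.0), (3, 4, 4, 4)),
        "elevation": ((200.0, 500.0), (3, 4, 4)),
        "ph": ((5.5, 6.5, 7.5, 8.5), (3, 4, 4, 3, 3)),
        "sc": ((200.0, 600.0), (3, 4, 4)),
    },
    "GL": {
        "slope": ((5.0, 15.0, 25.0), (4, 4, 4, 3)),
        "elevation": ((200.0, 500.0), (3, 4, 4)),
        "ph": ((5.5, 6.5, 7.5, 8.5), (3, 4, 4, 3, 3)),
        "sc": ((200.0, 600.0), (3, 4, 4)),
    },
    "SL": {
        "slope": ((5.0, 15.0, 25.0), (3, 4, 4, 4)),
        "elevation": ((200.0, 500.0), (3, 4, 4)),
        "ph": ((5.5, 6.5, 7.5, 8.5), (3, 4, 4, 3, 3)),
        "sc": ((200.0, 600.0), (3, 4, 4)),
    },
}

#: Cropland absolute exclusion: the steep-slope (≥ 25°) farming ban.
CL_SLOPE_EXCLUSION_DEG = 25.0


def load_criteria_yaml(path) -> dict[str, dict[str, tuple]]:
    """Load a criterion table from YAML.

    Expected layout::

        CL:
          slope: {breakpoints: [5, 15, 25], grades: [4, 3, 2, 1]}
          ...

    Returns the same structure as :data:`DEFAULT_CRITERIA`.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    criteria: dict[str, dict[str, tuple]] = {}
    for label, table in raw.items():
        criteria[label] = {}
        for crit, spec_ in table.items():
            criteria[label][crit] = (
                tuple(float(b) for b in spec_["breakpoints"]),
                tuple(spec_["grades"]),
            )
    return criteria


def build_atlas(
    layers: dict[str, np.ndarray],
    cell_size: float,
    criteria: dict | None = None,
    weights: dict[str, np.ndarray] | None = None,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
) -> SuitabilityAtlas:
    """Grade every suitability class from named criterion layers.

    ``layers`` maps criterion names (``slope``, ``elevation``, ``ph``,
    ``slo``, ``sc``, ``wy``) to rasters; missing criteria are skipped for
    the classes that use them.  Per-class weights default to equal weights
    over the class's available criteria.
    """
    criteria = DEFAULT_CRITERIA if criteria is None else criteria
    atlas = SuitabilityAtlas(cell_size=cell_size)
    for label, spec_ in criteria.items():
        grades, used = [], []
        for crit, (bps, grd) in spec_.items():
            if crit in layers:
                grades.append(score_criterion(layers[crit], bps, grd))
                used.append(crit)
        if not grades:
            raise ValueError(f"no criterion layers available for class {label}")
        if weights and label in weights:
            w = np.asarray(weights[label], float)
        else:
            w = np.full(len(grades), 1.0 / len(grades))
        exclusion = None
        if label == "CL" and "slope" in layers:
            exclusion = np.asarray(layers["slope"], float) >= CL_SLOPE_EXCLUSION_DEG
        score, grade = composite_suitability(grades, w, exclusion, thresholds)
        atlas.add(label, score, grade)
    return atlas

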