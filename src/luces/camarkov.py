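"""CA-Markov scenario simulation: Markov demand projection, cellular-
automaton spatial allocation with a 5×5 Moore filter, and kappa validation.

The Markov stage answers *how much*: projected class areas are
``start_areas · Pⁿ`` for a row-stochastic period matrix ``P``.  The CA
stage answers *where*: over ``n_iterations`` passes, per-class interim
quotas interpolate linearly from the current composition to the demand
(IDRISI-style annual slicing), and each pass reassigns cells by a claim
score

    score_c(cell) = suitability_c(cell) × (f_c(cell) + ε)

where ``f_c`` is the class-c fraction of the 5×5 Moore window around the
cell (centre excluded, truncated at edges) and ε keeps cells with an empty
neighbourhood allocatable (new patches can seed, but are disfavoured).
Only net changes move: classes whose interim quota exceeds their current
count claim the difference, in descending claim-score order, from cells of
classes below quota (ties broken by a seeded permutation); every other cell
keeps its class.  A demand equal to the current composition therefore
reproduces the input map exactly, and there is no gratuitous churn.

Validation uses the kappa statistic kappa = (Po − Pc)/(Pp − Pc) with
Po the observed cellwise agreement, Pc the chance agreement from the two
maps' marginal class shares, and Pp = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import CLASS_CODES, LEGEND, LandCoverGrid, check_aligned
from .suitability import SuitabilityAtlas
from .synthetic import check_stochastic
from .transitions import cross_tabulate

NEIGHBORHOOD = 5          # Moore window edge (cells)
CLAIM_EPSILON = 0.01      # ε in the claim score

#: Default iteration counts: a 10-iteration hindcast run and a 16-iteration
#: horizon run.
DEFAULT_ITER_HINDCAST = 10
DEFAULT_ITER_FORECAST = 16


@dataclass
class DemandVector:
    """Per-class target areas (km²) for a horizon year."""

    areas: np.ndarray
    provenance: str = "user"   # markov | optimizer | user
    labels: tuple[str, ...] = tuple(LEGEND.values())

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas < 0).any():
            raise ValueError("demand areas must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.areas.sum())


@dataclass
class KappaResult:
    po: float
    pc: float
    pp: float = 1.0

    @property
    def kappa(self) -> float:
        return (self.po - self.pc) / (self.pp - self.pc)


def markov_project(
    probabilities: np.ndarray, start_areas: np.ndarray, n_periods: int
) -> DemandVector:
    """Project class areas ``n_periods`` steps: demand = areas · Pⁿ."""
    check_stochastic(probabilities)
    P = np.asarray(probabilities, dtype=float)
    areas = np.asarray(start_areas, dtype=float)
    if (areas < 0).any():
        raise ValueError("start areas must be nonnegative")
    demand = areas @ np.linalg.matrix_power(P, n_periods)
    return DemandVector(demand, provenance="markov")


def _largest_remainder_counts(target_areas: np.ndarray, cell_area: float, total_cells: int) -> np.ndarray:
    """Integer cell quotas summing exactly to ``total_cells``, proportional
    to the target areas (largest-remainder rounding)."""
    shares = np.asarray(target_areas, float) / cell_area
    shares = shares * (total_cells / shares.sum())
    base = np.floor(shares).astype(int)
    rem = total_cells - base.sum()
    order = np.argsort(-(shares - base), kind="stable")
    base[order[:rem]] += 1
    return base


def _neighbor_fractions(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Per-class fraction of the 5×5 Moore window (centre excluded),
    truncated windows normalized by their actual valid size."""
    k = NEIGHBORHOOD
    counts = np.empty((len(CLASS_CODES),) + values.shape)
    kernel_sum = lambda arr: ndimage.uniform_filter(arr, size=k, mode="constant") * k * k
    denom = kernel_sum(valid.astype(float)) - valid.astype(float)
    denom = np.maximum(denom, 1.0)
    for i, code in enumerate(CLASS_CODES):
        mask = ((values == code) & valid).astype(float)
        counts[i] = (kernel_sum(mask) - mask) / denom
    return counts


def _suitability_cube(atlas: SuitabilityAtlas | None, shape) -> np.ndarray:
    """Stack per-class suitability scores; classes without a surface get a
    uniform one."""
    cube = np.ones((len(CLASS_CODES),) + tuple(shape))
    if atlas is not None:
        for i, code in enumerate(CLASS_CODES):
            label = LEGEND[code]
            if label in atlas.scores:
                s = np.nan_to_num(atlas.scores[label], nan=0.0)
                cube[i] = np.clip(s, 0.0, 1.0)
    return cube


def ca_allocate(
    current: LandCoverGrid,
    demand: DemandVector,
    atlas: SuitabilityAtlas | None = None,
    n_iterations: int = DEFAULT_ITER_FORECAST,
    seed: int = 0,
) -> LandCoverGrid:
    """Spatially allocate a demanded composition starting from a map.

    Final per-class cell counts match the demand to within rounding (the
    quotas are a largest-remainder integerization of the demanded areas, so
    each class lands within ±1 cell of ``demand/cell_area``).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    valid = current.valid_mask
    total_cells = int(valid.sum())
    cell_area = current.cell_area_km2
    if abs(demand.total - total_cells * cell_area) > cell_area + 1e-9:
        raise ValueError(
            f"demand total {demand.total:.6f} km² incompatible with valid area "
            f"{total_cells * cell_area:.6f} km²"
        )
    suit = _suitability_cube(atlas, current.shape)
    start_counts = np.array(
        [np.count_nonzero((current.values == c) & valid) for c in CLASS_CODES]
    )
    final_counts = _largest_remainder_counts(demand.areas, cell_area, total_cells)

    rng = np.random.default_rng(seed)
    values = current.values.copy()
    flat_valid = np.flatnonzero(valid.ravel())

    for t in range(1, n_iterations + 1):
        frac = t / n_iterations
        interim_areas = start_counts * (1 - frac) + final_counts * frac
        quotas = _largest_remainder_counts(
            np.maximum(interim_areas, 0) * cell_area, cell_area, total_cells
        )
        cur = values.ravel()[flat_valid]
        counts = np.bincount(cur - 1, minlength=len(CLASS_CODES))
        delta = quotas - counts
        claim = np.maximum(delta, 0)           # cells each class must gain
        release = np.maximum(-delta, 0)        # cells each class must shed
        if claim.sum() == 0:
            continue

        f = _neighbor_fractions(values, valid)
        scores = suit * (f + CLAIM_EPSILON)         # (9, rows, cols)
        flat_scores = scores.reshape(len(CLASS_CODES), -1)[:, flat_valid]

        # candidate pairs: growing class × cell currently in a shrinking class
        growing = np.flatnonzero(claim > 0)
        donors = np.flatnonzero(np.isin(cur - 1, np.flatnonzero(release > 0)))
        sub = flat_scores[np.ix_(growing, donors)]
        tie = rng.permutation(sub.size)
        order = np.lexsort((tie, -sub.ravel()))
        cls_idx, cell_idx = np.unravel_index(order, sub.shape)

        new_class = cur.copy()
        taken = np.zeros(donors.size, dtype=bool)
        to_place = int(claim.sum())
        for ci, pj in zip(cls_idx, cell_idx):
            if taken[pj]:
                continue
            gi = growing[ci]
            if claim[gi] == 0:
                continue
            src = cur[donors[pj]] - 1
            if release[src] == 0:
                continue
            new_class[donors[pj]] = gi + 1
            claim[gi] -= 1
            release[src] -= 1
            taken[pj] = True
            to_place -= 1
            if to_place == 0:
                break

        new_flat = values.ravel().copy()
        new_flat[flat_valid] = new_class
        values = new_flat.reshape(values.shape)

    out = LandCoverGrid(values, current.cell_size, current.nodata)
    return out


def kappa(reference: LandCoverGrid, simulated: LandCoverGrid) -> KappaResult:
    """Chance-corrected agreement between two aligned categorical maps."""
    check_aligned(reference, simulated)
    valid = reference.valid_mask & simulated.valid_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no jointly valid cells")
    r = reference.values[valid]
    s = simulated.values[valid]
    po = float(np.mean(r == s))
    pc = 0.0
    for code in CLASS_CODES:
        pc += np.mean(r == code) * np.mean(s == code)
    return KappaResult(po, float(pc))


def per_class_kappa(reference: LandCoverGrid, simulated: LandCoverGrid) -> dict[str, float | None]:
    """Kappa of each class's binary presence map; ``None`` when the class is
    absent from both maps (kappa undefined, not zero)."""
    check_aligned(reference, simulated)
    valid = reference.valid_mask & simulated.valid_mask
    r = reference.values[valid]
    s = simulated.values[valid]
    out: dict[str, float | None] = {}
    for code in CLASS_CODES:
        rb = r == code
        sb = s == code
        if not rb.any() and not sb.any():
            out[LEGEND[code]] = None
            continue
        po = float(np.mean(rb == sb))
        pc = float(np.mean(rb) * np.mean(sb) + np.mean(~rb) * np.mean(~sb))
        out[LEGEND[code]] = (po - pc) / (1.0 - pc) if pc < 1.0 else None
    return out


@dataclass
class HindcastResult:
    overall: KappaResult
    per_class: dict[str, float | None]
    simulated: LandCoverGrid


def validate_hindcast(
    series: list[LandCoverGrid],
    atlas: SuitabilityAtlas | None = None,
    n_iterations: int = DEFAULT_ITER_HINDCAST,
    seed: int = 0,
) -> HindcastResult:
    """Calibrate on the first interval of a ≥3-date series, simulate the
    last date, and score the simulation against it."""
    if len(series) < 3:
        raise ValueError("hindcast needs at least 3 dates")
    first, second, reference = series[0], series[1], series[-1]
    matrix = cross_tabulate(first, second)
    from .grid import area_vector

    n_periods = len(series) - 2  # intervals from the second date to the last
    demand = markov_project(matrix.probabilities, area_vector(second), n_periods)
    simulated = ca_allocate(second, demand, atlas, n_iterations=n_iterations, seed=seed)
    return HindcastResult(
        overall=kappa(reference, simulated),
        per_class=per_class_kappa(reference, simulated),
        simulated=simulated,
    )
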