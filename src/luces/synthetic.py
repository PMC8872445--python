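"""Synthetic raster stacks and land-cover time series with known structure.

The generator emulates a mountainous district raster stack: a skewed
elevation distribution with three terrain strata (plain ≤ 200 m, hill
200–500 m, mountain ≥ 500 m, with the mountain stratum dominant), smooth
climate and soil surfaces, and a land-cover time series driven by a known
Markov transition matrix.  Every output is a deterministic function of one
master seed; per-layer sub-streams are derived by fixed offsets so adding a
layer never perturbs the others.

Cells evolve independently in :func:`simulate_series` — there is no spatial
interaction — which makes the series an exact sampling null for
transition-matrix recovery tests; spatial (CA) behaviour is tested
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import (
    CLASS_CODES,
    FLAT_ASPECT,
    GridError,
    LandCoverGrid,
    Raster,
    RasterStack,
)

# Stratum boundaries (m) and target area shares of the emulated district:
# plain below 200 m (~6 %), hills 200–500 m (~23 %), mountains above (~71 %).
STRATUM_EDGES = (200.0, 500.0)
STRATUM_SHARES = (0.06, 0.23, 0.71)

# Fixed sub-stream offsets per layer (master seed + offset).
_STREAMS = {
    "dem": 11,
    "precipitation": 13,
    "et0": 17,
    "awc": 19,
    "erosivity": 23,
    "erodibility": 29,
    "ph": 31,
    "lucc": 37,
    "series": 41,
}


def _default_affinity() -> np.ndarray:
    """Class terrain affinity, rows = classes in legend order, cols = strata.

    Cropland, orchard and built-up land concentrate on the plain; shrubs and
    grass on the hills; forest, shrubs and bare rock in the mountains.
    """
    return np.array(
        [
            # plain, hill, mountain
            [5.0, 1.0, 0.1],   # CL
            [4.0, 2.0, 0.2],   # OC
            [0.5, 3.0, 6.0],   # FL
            [0.5, 4.0, 5.0],   # SL
            [1.0, 3.0, 1.5],   # GL
            [0.2, 0.3, 0.8],   # BL
            [1.5, 0.3, 0.1],   # WB
            [1.0, 1.5, 0.5],   # WL
            [6.0, 0.8, 0.05],  # BUL
        ]
    )


def _default_transition(persistence: float = 0.92) -> np.ndarray:
    """Diagonal-dominant row-stochastic matrix: mostly persistent classes
    with the off-diagonal mass spread uniformly."""
    n = len(CLASS_CODES)
    off = (1.0 - persistence) / (n - 1)
    mat = np.full((n, n), off)
    np.fill_diagonal(mat, persistence)
    return mat


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic district.

    ``elevation_range`` spans valley floor to summit; the DEM's quantiles are
    warped so the three strata hit the configured shares.  ``smooth_cells``
    is the Gaussian kernel width used for every random field.
    """

    shape: tuple[int, int] = (100, 100)
    cell_size: float = 30.0
    seed: int = 0
    elevation_range: tuple[float, float] = (80.0, 1500.0)
    smooth_cells: float = 5.0
    class_affinity: np.ndarray = field(default_factory=_default_affinity)
    true_transition: np.ndarray = field(default_factory=_default_transition)
    n_steps: int = 3

    def __post_init__(self) -> None:
        self.class_affinity = np.asarray(self.class_affinity, dtype=float)
        self.true_transition = np.asarray(self.true_transition, dtype=float)
        check_stochastic(self.true_transition)


def check_stochastic(matrix: np.ndarray, tol: float = 1e-9) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"transition matrix must be square, got {matrix.shape}")
    if (matrix < 0).any():
        raise ValueError("transition matrix has negative entries")
    sums = matrix.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=tol):
        raise ValueError(f"transition rows must sum to 1, got {sums}")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    field_ -= field_.mean()
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _scaled_field(rng, shape, sigma, lo, hi) -> np.ndarray:
    """Smooth field rescaled to [lo, hi] by min-max."""
    f = _smooth_field(rng, shape, sigma)
    f = (f - f.min()) / (f.max() - f.min() + 1e-12)
    return lo + f * (hi - lo)


def _skewed_dem(rng, shape, sigma, elevation_range) -> np.ndarray:
    """DEM whose stratum shares match :data:`STRATUM_SHARES`.

    The smoothed field is rank-transformed to uniform, then passed through a
    piecewise-linear quantile function with knots at the stratum boundaries.
    """
    lo, hi = elevation_range
    f = _smooth_field(rng, shape, sigma)
    ranks = f.flatten().argsort().argsort().astype(float)
    u = (ranks + 0.5) / ranks.size
    p1, p2 = STRATUM_SHARES[0], STRATUM_SHARES[0] + STRATUM_SHARES[1]
    e1, e2 = STRATUM_EDGES
    dem = np.empty_like(u)
    low = u < p1
    mid = (u >= p1) & (u < p2)
    high = u >= p2
    dem[low] = lo + (u[low] / p1) * (e1 - lo)
    dem[mid] = e1 + ((u[mid] - p1) / (p2 - p1)) * (e2 - e1)
    dem[high] = e2 + ((u[high] - p2) / (1 - p2)) * (hi - e2)
    return dem.reshape(shape)


def horn_slope_aspect(dem: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and aspect (degrees from north, clockwise) by Horn's
    3×3 finite differences; edges use replicated borders.  Flat cells get
    aspect :data:`FLAT_ASPECT`."""
    z = np.pad(dem, 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # downslope compass direction: east component -dzdx, north component +dzdy
    aspect = np.degrees(np.arctan2(-dzdx, dzdy)) % 360.0  # north = 0, clockwise
    aspect[slope == 0] = FLAT_ASPECT
    return slope, aspect


def make_terrain(config: SyntheticConfig) -> RasterStack:
    """Generate the full continuous stack for the configured district."""
    shape = tuple(config.shape)
    if shape[0] < 3 or shape[1] < 3:
        raise GridError("terrain shape must be at least 3×3 (slope undefined)")
    sigma = config.smooth_cells
    cs = config.cell_size

    def rng(layer):
        return np.random.default_rng(config.seed + _STREAMS[layer])

    dem = _skewed_dem(rng("dem"), shape, sigma, config.elevation_range)
    slope, aspect = horn_slope_aspect(dem, cs)

    # Precipitation rises modestly with elevation (orographic gradient).
    lo, hi = config.elevation_range
    rel = (dem - lo) / (hi - lo)
    precipitation = _scaled_field(rng("precipitation"), shape, sigma, 420.0, 560.0) + 120.0 * rel
    et0 = _scaled_field(rng("et0"), shape, sigma, 820.0, 1060.0) - 80.0 * rel
    awc = _scaled_field(rng("awc"), shape, sigma, 90.0, 260.0)
    erosivity = _scaled_field(rng("erosivity"), shape, sigma, 1500.0, 3200.0)
    erodibility = _scaled_field(rng("erodibility"), shape, sigma, 0.015, 0.045)
    ph = _scaled_field(rng("ph"), shape, sigma, 5.6, 8.4)

    stack = RasterStack()
    for name, values in [
        ("dem", dem), ("slope", slope), ("aspect", aspect),
        ("precipitation", precipitation), ("et0", et0), ("awc", awc),
        ("erosivity", erosivity), ("erodibility", erodibility), ("ph", ph),
    ]:
        stack.add(name, Raster(values, cell_size=cs))
    return stack


def elevation_strata(dem: np.ndarray) -> np.ndarray:
    """Stratum index per cell: 0 plain, 1 hill, 2 mountain."""
    return np.digitize(dem, STRATUM_EDGES)


def make_initial_lucc(
    terrain: RasterStack,
    affinity: np.ndarray | None = None,
    seed: int = 0,
    cell_size: float | None = None,
) -> LandCoverGrid:
    """Sample an initial land-cover map with terrain-dependent class mix.

    Within each elevation stratum the class of a cell is drawn with
    probability proportional to the stratum's affinity column.
    """
    affinity = _default_affinity() if affinity is None else np.asarray(affinity, float)
    if (affinity < 0).any():
        raise ValueError("affinity weights must be nonnegative")
    col_sums = affinity.sum(axis=0)
    if (col_sums <= 0).any():
        raise ValueError("every stratum needs at least one positive affinity")
    dem = terrain["dem"].values
    strata = elevation_strata(dem)
    rng = np.random.default_rng(seed + _STREAMS["lucc"])
    u = rng.random(dem.shape)
    values = np.empty(dem.shape, dtype=np.int64)
    for s in range(affinity.shape[1]):
        probs = affinity[:, s] / col_sums[s]
        cum = np.cumsum(probs)
        sel = strata == s
        values[sel] = np.searchsorted(cum, u[sel], side="right") + 1
    np.clip(values, 1, len(CLASS_CODES), out=values)
    return LandCoverGrid(values, cell_size=cell_size or terrain.cell_size)


def simulate_series(
    initial: LandCoverGrid,
    true_transition: np.ndarray,
    n_steps: int,
    seed: int = 0,
) -> list[LandCoverGrid]:
    """Evolve each cell as an independent Markov chain.

    Returns ``[initial, step1, ..., stepN]``; deterministic given the seed.
    """
    check_stochastic(true_transition)
    P = np.asarray(true_transition, dtype=float)
    cum = np.cumsum(P, axis=1)
    rng = np.random.default_rng(seed + _STREAMS["series"])
    series = [initial.copy()]
    current = initial.values.copy()
    valid = initial.valid_mask
    for _ in range(n_steps):
        u = rng.random(current.shape)
        nxt = current.copy()
        for code in CLASS_CODES:
            sel = (current == code) & valid
            if sel.any():
                nxt[sel] = np.searchsorted(cum[code - 1], u[sel], side="right") + 1
        np.clip(nxt, 1, len(CLASS_CODES), out=nxt)
        nxt[~valid] = initial.nodata
        series.append(LandCoverGrid(nxt, initial.cell_size, initial.nodata))
        current = nxt
    return series
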