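"""Grey-linear scenario optimization: GM(1,1) area forecasting, a linear
program for the land-use quantity structure, and suitability-priority
spatial allocation.

GM(1,1) fits the whitening equation dx¹/dt + a·x¹ = b on the cumulative
series x¹ by least squares with background values
z(k) = ½(x¹(k) + x¹(k−1)), then forecasts
x̂⁰(k) = (1 − eᵃ)(x⁰(1) − b/a)e^{−a(k−1)}.

The quantity LP maximizes a weighted ecology + economy benefit over the
nine class areas subject to an exact total-area constraint, per-class
bounds (grey forecasts ± tolerance, policy locks) and optional capacity
caps from the suitability atlas; equal emphasis on ecology and economy
(weights ½/½) is the default.

Spatial allocation then hands each class, in priority order (scarcest
environmental requirements first), its demanded cell count from the
highest-suitability unclaimed cells, preferring persistence at equal
suitability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .camarkov import DemandVector, _largest_remainder_counts, _suitability_cube
from .grid import CLASS_CODES, CODES, LEGEND, LandCoverGrid
from .suitability import SuitabilityAtlas

# ---------------------------------------------------------------------------
# GM(1,1) grey forecasting
# ---------------------------------------------------------------------------


@dataclass
class GreyModel:
    """Fitted GM(1,1): development coefficient ``a`` and grey input ``b``."""

    a: float
    b: float
    x0: np.ndarray                       # observed series
    fitted: np.ndarray                   # in-sample reconstruction
    relative_errors: np.ndarray          # |fit - obs| / obs, points 2..n

    def forecast(self, horizon: int) -> np.ndarray:
        """Forecast ``horizon`` steps past the series end; horizon 0 returns
        the last observed value."""
        n = len(self.x0)
        if horizon == 0:
            return np.array([self.x0[-1]])
        ks = np.arange(n + 1, n + horizon + 1)
        return _gm_values(self.a, self.b, self.x0[0], ks)


def _gm_values(a: float, b: float, x0_1: float, ks: np.ndarray) -> np.ndarray:
    """x̂⁰(k) for k ≥ 2 via the closed form; a → 0 reduces to the constant b."""
    ks = np.asarray(ks, dtype=float)
    if abs(a) < 1e-12:
        return np.full(ks.shape, b)
    return (1.0 - np.exp(a)) * (x0_1 - b / a) * np.exp(-a * (ks - 1.0))


def grey_fit(series) -> GreyModel:
    """Fit GM(1,1) to a positive series of length ≥ 4."""
    x0 = np.asarray(series, dtype=float)
    if len(x0) < 4:
        raise ValueError(f"GM(1,1) needs at least 4 observations, got {len(x0)}")
    if (x0 <= 0).any():
        raise ValueError("GM(1,1) is undefined for non-positive series entries")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z, np.ones(len(z))])
    coef, *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    a, b = float(coef[0]), float(coef[1])
    ks = np.arange(2, len(x0) + 1)
    fitted = np.concatenate([[x0[0]], _gm_values(a, b, x0[0], ks)])
    rel = np.abs(fitted[1:] - x0[1:]) / x0[1:]
    return GreyModel(a, b, x0, fitted, rel)


def grey_forecast(series, horizon: int) -> np.ndarray:
    """Convenience wrapper: fit then forecast."""
    return grey_fit(series).forecast(horizon)


# ---------------------------------------------------------------------------
# Quantity-structure linear program
# ---------------------------------------------------------------------------


class InfeasibleStructureError(ValueError):
    """Raised when the LP constraint set admits no solution."""


@dataclass
class StructureLP:
    """Land-use quantity structure program over the nine class areas (km²).

    ``eco_benefit`` and ``econ_benefit`` are per-km² coefficients by class
    label; the objective maximizes ``Σ (w_eco·eco + w_econ·econ)·x``.
    ``lower``/``upper`` are per-class bounds (defaults 0 / total).
    ``equalities`` pins classes to exact areas (policy locks).
    """

    total_area: float
    eco_benefit: dict[str, float]
    econ_benefit: dict[str, float]
    w_eco: float = 0.5
    w_econ: float = 0.5
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    equalities: dict[str, float] = field(default_factory=dict)


def solve_structure(lp: StructureLP) -> DemandVector:
    """Solve the quantity LP; returns an optimizer-provenance demand.

    Raises :class:`InfeasibleStructureError` listing the active constraint
    set when no feasible point exists — constraints are never silently
    relaxed.
    """
    labels = [LEGEND[c] for c in CLASS_CODES]
    c = -np.array(
        [lp.w_eco * lp.eco_benefit.get(l, 0.0) + lp.w_econ * lp.econ_benefit.get(l, 0.0)
         for l in labels]
    )
    bounds = []
    for l in labels:
        if l in lp.equalities:
            v = lp.equalities[l]
            bounds.append((v, v))
        else:
            bounds.append((lp.lower.get(l, 0.0), lp.upper.get(l, lp.total_area)))
    A_eq = np.ones((1, len(labels)))
    b_eq = np.array([lp.total_area])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        detail = ", ".join(
            f"{l}∈[{lo:.4g},{hi:.4g}]" for l, (lo, hi) in zip(labels, bounds)
        )
        raise InfeasibleStructureError(
            f"no feasible structure: total={lp.total_area:.4g}, bounds {detail}"
        )
    return DemandVector(res.x, provenance="optimizer")


def check_feasible(lp: StructureLP, areas: dict[str, float], tol: float = 1e-6) -> bool:
    """Whether a given composition satisfies the LP's constraint set."""
    labels = [LEGEND[c] for c in CLASS_CODES]
    x = np.array([areas.get(l, 0.0) for l in labels])
    if abs(x.sum() - lp.total_area) > tol:
        return False
    for i, l in enumerate(labels):
        if l in lp.equalities and abs(x[i] - lp.equalities[l]) > tol:
            return False
        if x[i] < lp.lower.get(l, 0.0) - tol:
            return False
        if x[i] > lp.upper.get(l, lp.total_area) + tol:
            return False
    return True


# ---------------------------------------------------------------------------
# Suitability-priority spatial allocation
# ---------------------------------------------------------------------------

#: Classes with demanding environmental requirements claim space first;
#: the rest fill the residual.  Config-overridable.
DEFAULT_PRIORITY = ("CL", "OC", "FL", "GL", "SL")

_PERSIST_BONUS = 1e-9  # prefers staying put only at exactly equal suitability


def priority_allocate(
    current: LandCoverGrid,
    demand: DemandVector,
    atlas: SuitabilityAtlas | None = None,
    priority_order=DEFAULT_PRIORITY,
    seed: int = 0,
) -> LandCoverGrid:
    """Allocate a demanded composition by strict suitability priority.

    Classes in ``priority_order`` claim their demanded cell counts from the
    highest-suitability unclaimed cells (persistence wins ties); remaining
    classes then fill the residual cells by their own descending
    suitability, in descending residual-demand order.
    """
    valid = current.valid_mask
    total_cells = int(valid.sum())
    cell_area = current.cell_area_km2
    if demand.total > total_cells * cell_area + cell_area + 1e-9:
        raise ValueError(
            f"demand total {demand.total:.6f} km² exceeds valid area "
            f"{total_cells * cell_area:.6f} km²"
        )
    quotas = _largest_remainder_counts(demand.areas, cell_area, total_cells)
    suit = _suitability_cube(atlas, current.shape)
    rng = np.random.default_rng(seed)

    flat_valid = np.flatnonzero(valid.ravel())
    cur = current.values.ravel()[flat_valid]
    n = flat_valid.size
    assigned = np.full(n, -1, dtype=int)
    tie = rng.random(n)

    prio_codes = [CODES[l] for l in priority_order]
    rest = [c for c in CLASS_CODES if c not in prio_codes]
    rest.sort(key=lambda c: -quotas[c - 1])

    for code in prio_codes + rest:
        i = code - 1
        q = quotas[i]
        if q == 0:
            continue
        free = np.flatnonzero(assigned < 0)
        s = suit[i].ravel()[flat_valid][free]
        persist = (cur[free] == code).astype(float) * _PERSIST_BONUS
        order = np.lexsort((tie[free], -(s + persist)))
        take = free[order[:q]]
        assigned[take] = i

    # any residual cells (numerical corner) keep their current class
    left = assigned < 0
    assigned[left] = cur[left] - 1

    out_flat = current.values.ravel().copy()
    out_flat[flat_valid] = assigned + 1
    return LandCoverGrid(
        out_flat.reshape(current.shape), current.cell_size, current.nodata
    )
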