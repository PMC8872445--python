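"""Ecosystem-service assessment: annual water yield, soil loss and
conservation, and carbon stocks, with landscape totals.

Water yield follows the Budyko-curve annual water balance used by
InVEST-style models: per cell, yield Y = P − TAE where for vegetated
classes TAE/P = (1 + wR) / (1 + wR + 1/R) with dryness index
R = Kc·ET0 / P and soil-water term w = Z·AWC/P + 1.25 (Z the seasonal
constant), while open water, built-up and bare classes use the direct
evaporation clamp TAE = min(Kc·ET0, P).

Soil accounting uses the (R)USLE factors: potential loss USLE = R·K·LS,
actual loss RUSLE = R·K·LS·C·P, and sediment retention
SEDRET = USLE − RUSLE + SED, where SED is sediment arriving from upslope
cells along single-direction (D8) flow paths that the receiving cell's
cover intercepts.

Carbon stock is composition-only: per-class density (tC/ha, the four pools
aggregated) times class area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CLASS_CODES, CODES, LEGEND, LandCoverGrid, Raster, RasterStack

#: Vegetated classes use the Budyko curve; the rest use the min-clamp.
VEGETATED = ("CL", "OC", "FL", "SL", "GL", "WL")
NON_VEGETATED = ("BL", "WB", "BUL")


def _per_class(d: dict[str, float]) -> np.ndarray:
    return np.array([d[LEGEND[c]] for c in CLASS_CODES], dtype=float)


@dataclass
class WaterYieldParams:
    """Per-class evapotranspiration coefficients Kc and the seasonal
    constant Z.  The Kc table is a documented default, overridable from a
    CSV keyed by class code."""

    kc: dict[str, float] = field(default_factory=lambda: {
        "CL": 0.65, "OC": 0.75, "FL": 1.0, "SL": 0.8, "GL": 0.65,
        "BL": 0.2, "WB": 1.1, "WL": 0.5, "BUL": 0.3,
    })
    z: float = 9.0

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("Z must be positive")
        if any(v <= 0 for v in self.kc.values()):
            raise ValueError("Kc coefficients must be positive")


@dataclass
class ErosionParams:
    """Per-class cover (C), practice (P) and sediment-retention efficiency
    tables; documented defaults, overridable."""

    c_factor: dict[str, float] = field(default_factory=lambda: {
        "CL": 0.22, "OC": 0.15, "FL": 0.004, "SL": 0.01, "GL": 0.04,
        "BL": 1.0, "WB": 0.0, "WL": 0.25, "BUL": 0.0,
    })
    p_factor: dict[str, float] = field(default_factory=lambda: {
        "CL": 0.35, "OC": 0.5, "FL": 1.0, "SL": 1.0, "GL": 1.0,
        "BL": 1.0, "WB": 0.0, "WL": 1.0, "BUL": 0.0,
    })
    retention_efficiency: dict[str, float] = field(default_factory=lambda: {
        "CL": 0.25, "OC": 0.4, "FL": 0.6, "SL": 0.5, "GL": 0.35,
        "BL": 0.05, "WB": 0.0, "WL": 0.35, "BUL": 0.0,
    })

    def __post_init__(self) -> None:
        for name, table in [("C", self.c_factor), ("P", self.p_factor),
                            ("retention", self.retention_efficiency)]:
            for k, v in table.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} factor for {k} must be in [0, 1], got {v}")


#: Per-class carbon densities (tC/ha), aggregate over the above/below-ground,
#: soil and dead pools; open water and built-up land carry none.
DEFAULT_CARBON_DENSITY: dict[str, float] = {
    "CL": 30.96, "OC": 30.96, "FL": 150.40, "SL": 118.42, "GL": 96.68,
    "BL": 10.00, "WB": 0.0, "WL": 96.68, "BUL": 0.0,
}


@dataclass
class ESResult:
    """Per-cell service rasters plus landscape totals."""

    rasters: dict[str, np.ndarray] = field(default_factory=dict)
    totals: dict[str, float] = field(default_factory=dict)
    cell_size: float = 30.0


# ---------------------------------------------------------------------------
# Water yield
# ---------------------------------------------------------------------------

def water_yield(
    stack: RasterStack, lucc: LandCoverGrid, params: WaterYieldParams | None = None
) -> ESResult:
    """Annual water yield per cell (mm) and landscape total (m³)."""
    params = params or WaterYieldParams()
    P = stack["precipitation"].values
    et0 = stack["et0"].values
    awc = stack["awc"].values
    valid = lucc.valid_mask & ~np.isnan(P) & ~np.isnan(et0) & ~np.isnan(awc)
    if (P[valid] <= 0).any():
        idx = tuple(int(i) for i in np.argwhere(valid & (P <= 0))[0])
        raise ValueError(f"precipitation must be positive on valid cells; cell {idx}")
    if (awc[valid] < 0).any():
        idx = tuple(int(i) for i in np.argwhere(valid & (awc < 0))[0])
        raise ValueError(f"negative available water content at cell {idx}")

    kc = _per_class(params.kc)
    kc_map = np.zeros(lucc.shape)
    veg = np.zeros(lucc.shape, dtype=bool)
    veg_codes = {CODES[l] for l in VEGETATED}
    for i, code in enumerate(CLASS_CODES):
        sel = lucc.values == code
        kc_map[sel] = kc[i]
        if code in veg_codes:
            veg[sel] = True

    tae = np.full(lucc.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tpe = kc_map * et0
        R = tpe / P
        w = params.z * (awc / P) + 1.25
        budyko = (1.0 + w * R) / (1.0 + w * R + 1.0 / R)
    sel_v = valid & veg
    tae[sel_v] = (P * budyko)[sel_v]
    sel_n = valid & ~veg
    tae[sel_n] = np.minimum(tpe, P)[sel_n]
    y = np.where(valid, np.clip(P - tae, 0.0, None), np.nan)

    cell_m2 = lucc.cell_size**2
    total_m3 = float(np.nansum(y) * cell_m2 / 1000.0)
    return ESResult(
        rasters={"water_yield_mm": y, "tae_mm": tae},
        totals={"WY_m3": total_m3},
        cell_size=lucc.cell_size,
    )


# ---------------------------------------------------------------------------
# D8 routing and the LS factor
# ---------------------------------------------------------------------------

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def d8_flow(dem: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """D8 flow direction and accumulation.

    Returns ``(receiver, accumulation)`` where ``receiver`` holds the flat
    index of each cell's steepest-descent neighbour (−1 for pits/flats, which
    do not drain) and ``accumulation`` counts contributing cells including
    the cell itself.  Ties take the first neighbour in row-major scan order.
    """
    rows, cols = dem.shape
    n = dem.size
    flat = dem.ravel()
    receiver = np.full(n, -1, dtype=np.int64)
    best_drop = np.zeros(n)
    for dr, dc in _D8:
        dist = np.hypot(dr, dc) * cell_size
        # off-grid neighbours are +inf so border cells never drain outward
        shifted = np.full((rows, cols), np.inf)
        r0, r1 = max(dr, 0), rows + min(dr, 0)
        c0, c1 = max(dc, 0), cols + min(dc, 0)
        shifted[r0 - dr : r1 - dr, c0 - dc : c1 - dc] = dem[r0:r1, c0:c1]
        drop = (dem - shifted) / dist
        drop = drop.ravel()
        idx = np.arange(n)
        nb = idx + dr * cols + dc
        better = drop > best_drop + 1e-12
        best_drop = np.where(better, drop, best_drop)
        receiver = np.where(better, nb, receiver)

    order = np.argsort(flat, kind="stable")[::-1]  # high to low
    acc = np.ones(n, dtype=np.int64)
    for i in order:
        r = receiver[i]
        if r >= 0:
            acc[r] += acc[i]
    return receiver, acc.reshape(dem.shape)


def ls_factor(dem: Raster) -> np.ndarray:
    """Moore–Burch slope-length-gradient factor.

    ``LS = (A·cell / 22.13)^0.4 · (sin θ / 0.0896)^1.3`` with A the D8 flow
    accumulation in cells and θ the Horn slope.  Flat terrain gives LS = 0.
    """
    from .synthetic import horn_slope_aspect

    slope_deg, _ = horn_slope_aspect(dem.values, dem.cell_size)
    _, acc = d8_flow(dem.values, dem.cell_size)
    sin_t = np.sin(np.radians(slope_deg))
    return (acc * dem.cell_size / 22.13) ** 0.4 * (sin_t / 0.0896) ** 1.3


# ---------------------------------------------------------------------------
# Soil budget
# ---------------------------------------------------------------------------

def soil_budget(
    stack: RasterStack,
    lucc: LandCoverGrid,
    params: ErosionParams | None = None,
    ls: np.ndarray | None = None,
) -> ESResult:
    """USLE/RUSLE soil loss, routed sediment interception and retention.

    Each cell's actual loss (RUSLE, t/ha) is exported along its D8 path;
    a downslope cell intercepts ``retention_efficiency`` of the load
    arriving at it (SED) and passes the rest on, so the cascade is traced
    from the highest cell down.  Totals: SLO = Σ RUSLE·area (t),
    SC = Σ SEDRET·area (t).
    """
    params = params or ErosionParams()
    R = stack["erosivity"].values
    K = stack["erodibility"].values
    dem = stack["dem"]
    if ls is None:
        ls = ls_factor(dem)
    valid = lucc.valid_mask & ~np.isnan(R) & ~np.isnan(K)

    cmap = np.zeros(lucc.shape)
    pmap = np.zeros(lucc.shape)
    eff = np.zeros(lucc.shape)
    for code in CLASS_CODES:
        label = LEGEND[code]
        sel = lucc.values == code
        cmap[sel] = params.c_factor[label]
        pmap[sel] = params.p_factor[label]
        eff[sel] = params.retention_efficiency[label]

    usle = np.where(valid, R * K * ls, np.nan)
    rusle = np.where(valid, usle * cmap * pmap, np.nan)

    receiver, _ = d8_flow(dem.values, dem.cell_size)
    flat_dem = dem.values.ravel()
    order = np.argsort(flat_dem, kind="stable")[::-1]
    load = np.nan_to_num(rusle, nan=0.0).ravel().copy()  # what each cell exports
    sed = np.zeros(dem.values.size)
    eff_flat = eff.ravel()
    valid_flat = valid.ravel()
    for i in order:
        r = receiver[i]
        if r < 0 or load[i] <= 0:
            continue
        incoming = load[i]
        intercepted = eff_flat[r] * incoming if valid_flat[r] else 0.0
        sed[r] += intercepted
        load[r] += incoming - intercepted

    sed = sed.reshape(dem.values.shape)
    sedret = np.where(valid, usle - rusle + sed, np.nan)

    cell_ha = lucc.cell_size**2 / 1e4
    return ESResult(
        rasters={"usle_t_ha": usle, "rusle_t_ha": rusle,
                 "sed_t_ha": np.where(valid, sed, np.nan), "sedret_t_ha": sedret},
        totals={"SLO_t": float(np.nansum(rusle) * cell_ha),
                "SC_t": float(np.nansum(sedret) * cell_ha)},
        cell_size=lucc.cell_size,
    )


# ---------------------------------------------------------------------------
# Carbon stock
# ---------------------------------------------------------------------------

def carbon_stock(
    lucc: LandCoverGrid, densities: dict[str, float] | None = None
) -> ESResult:
    """Landscape carbon stock: per-class density (tC/ha) × class area."""
    densities = densities or DEFAULT_CARBON_DENSITY
    missing = [LEGEND[c] for c in CLASS_CODES
               if LEGEND[c] not in densities and (lucc.values == c).any()]
    if missing:
        raise KeyError(f"missing carbon densities for classes {missing}")
    dmap = np.full(lucc.shape, np.nan)
    for code in CLASS_CODES:
        label = LEGEND[code]
        if label in densities:
            dmap[lucc.values == code] = densities[label]
    dmap[~lucc.valid_mask] = np.nan
    cell_ha = lucc.cell_size**2 / 1e4
    return ESResult(
        rasters={"carbon_t_ha": dmap},
        totals={"CS_t": float(np.nansum(dmap) * cell_ha)},
        cell_size=lucc.cell_size,
    )


def carbon_stock_from_areas(
    areas_km2: dict[str, float] | pd.Series, densities: dict[str, float] | None = None
) -> float:
    """Carbon stock (t) straight from a class-composition table (km²).

    Carbon is composition-only — the spatial arrangement is irrelevant — so
    a printed area table is a sufficient input.
    """
    densities = densities or DEFAULT_CARBON_DENSITY
    total = 0.0
    for label, km2 in dict(areas_km2).items():
        if label not in densities:
            raise KeyError(f"missing carbon density for class {label}")
        total += km2 * 100.0 * densities[label]  # km² -> ha
    return total


def assess_all(
    stack: RasterStack,
    lucc: LandCoverGrid,
    wy_params: WaterYieldParams | None = None,
    erosion_params: ErosionParams | None = None,
    densities: dict[str, float] | None = None,
) -> ESResult:
    """All four services on one land-cover map; rasters and totals merged."""
    wy = water_yield(stack, lucc, wy_params)
    soil = soil_budget(stack, lucc, erosion_params)
    carbon = carbon_stock(lucc, densities)
    out = ESResult(cell_size=lucc.cell_size)
    for part in (wy, soil, carbon):
        out.rasters.update(part.rasters)
        out.totals.update(part.totals)
    return out
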