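"""End-to-end orchestration of the seven-stage procedure.

Stages: transfer matrices on the observed series → suitability atlas →
CA hindcast validation → business-as-usual horizon prediction (scenario 1)
→ quantity optimization and priority allocation (scenario 2) → ecosystem-
service assessment of the base map and both scenarios → change tables.
Every stage logs its parameters; a run manifest (config, seed, package
version) is written beside the outputs so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .camarkov import (
    DEFAULT_ITER_FORECAST,
    DEFAULT_ITER_HINDCAST,
    ca_allocate,
    markov_project,
    validate_hindcast,
)
from .grid import RasterStack, area_vector, class_areas, read_grid, write_grid
from .metrics import compute_metrics
from .optimize import StructureLP, priority_allocate, solve_structure
from .services import ErosionParams, WaterYieldParams, assess_all
from .suitability import build_atlas, suitability_area_table
from .synthetic import SyntheticConfig, make_initial_lucc, make_terrain, simulate_series
from .transitions import cross_tabulate, export_transfer_table

log = logging.getLogger("luces")


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic or file-driven run."""

    out_dir: Path
    seed: int = 0
    shape: tuple[int, int] = (100, 100)
    cell_size: float = 30.0
    n_dates: int = 3
    iterations_hindcast: int = DEFAULT_ITER_HINDCAST
    iterations_forecast: int = DEFAULT_ITER_FORECAST
    horizon_periods: int = 2
    lucc_paths: list[Path] = field(default_factory=list)
    stack_paths: dict[str, Path] = field(default_factory=dict)
    param_files: dict[str, Path] = field(default_factory=dict)

    def validate(self) -> None:
        """Fail fast: every referenced file must exist before any stage runs."""
        missing = [str(p) for p in list(self.lucc_paths)
                   + list(self.stack_paths.values())
                   + list(self.param_files.values())
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {', '.join(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a run configuration from a YAML mapping.

        Recognized keys mirror the dataclass fields; ``shape`` is a two-item
        list, path fields are resolved relative to the config file.
        """
        import yaml

        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        root = path.parent

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else root / p

        kwargs: dict = {"out_dir": _resolve(raw.get("out_dir", "out"))}
        for key in ("seed", "cell_size", "n_dates", "iterations_hindcast",
                    "iterations_forecast", "horizon_periods"):
            if key in raw:
                kwargs[key] = raw[key]
        if "shape" in raw:
            kwargs["shape"] = tuple(raw["shape"])
        if "lucc_paths" in raw:
            kwargs["lucc_paths"] = [_resolve(p) for p in raw["lucc_paths"]]
        if "stack_paths" in raw:
            kwargs["stack_paths"] = {k: _resolve(p) for k, p in raw["stack_paths"].items()}
        if "param_files" in raw:
            kwargs["param_files"] = {k: _resolve(p) for k, p in raw["param_files"].items()}
        unknown = set(raw) - {
            "out_dir", "seed", "cell_size", "n_dates", "iterations_hindcast",
            "iterations_forecast", "horizon_periods", "shape", "lucc_paths",
            "stack_paths", "param_files",
        }
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**kwargs)


def compare_scenarios(totals: pd.DataFrame, base: str | None = None) -> pd.DataFrame:
    """Absolute and percent change of each service column against a base.

    ``totals`` is services × scenarios; percent change is
    (new − base)/base × 100 with the base column stated in the result.
    Full precision is retained; round only when printing.
    """
    if totals.shape[1] < 2:
        raise ValueError("need at least two scenarios to compare")
    base = base or totals.columns[0]
    rows = []
    for scenario in totals.columns:
        if scenario == base:
            continue
        for service in totals.index:
            b, v = totals.loc[service, base], totals.loc[service, scenario]
            rows.append({
                "service": service, "base": base, "scenario": scenario,
                "base_value": b, "value": v, "change": v - b,
                "pct_change": (v - b) / b * 100.0 if b != 0 else np.nan,
            })
    return pd.DataFrame(rows)


def _stage(name: str):
    log.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full procedure; returns the report bundle as a dict of
    DataFrames/paths and writes CSV outputs under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- inputs: load rasters or generate the synthetic district ----------
    if config.lucc_paths:
        series = [read_grid(p, "landcover") for p in config.lucc_paths]
        stack = RasterStack(
            {name: read_grid(p, "continuous") for name, p in config.stack_paths.items()}
        )
    else:
        _stage("synthesize")
        syn = SyntheticConfig(
            shape=config.shape, cell_size=config.cell_size, seed=config.seed
        )
        stack = make_terrain(syn)
        initial = make_initial_lucc(stack, syn.class_affinity, seed=config.seed)
        series = simulate_series(
            initial, syn.true_transition, config.n_dates - 1, seed=config.seed
        )
    base = series[-1]

    # --- stage 1: transfer matrices ---------------------------------------
    _stage("transitions")
    matrices = [
        cross_tabulate(a, b, f"t{i}", f"t{i+1}")
        for i, (a, b) in enumerate(zip(series, series[1:]))
    ]
    for i, m in enumerate(matrices):
        m.to_frame("areas").to_csv(out / f"transition_areas_{i}.csv")
        m.to_frame("probabilities").to_csv(out / f"transition_probabilities_{i}.csv")
        export_transfer_table(m, out / f"transfer_table_{i}.tsv")

    # --- landscape metrics per date ---------------------------------------
    _stage("metrics")
    metric_frames = []
    for i, g in enumerate(series):
        mt = compute_metrics(g)
        mt.insert(0, "date", f"t{i}")
        metric_frames.append(mt)
    metrics_table = pd.concat(metric_frames, ignore_index=True)
    metrics_table.to_csv(out / "landscape_metrics.csv", index=False)

    # --- stage 2: suitability atlas ----------------------------------------
    _stage("suitability")
    layers = {
        "slope": stack["slope"].values,
        "elevation": stack["dem"].values,
        "ph": stack["ph"].values,
    }
    atlas = build_atlas(layers, cell_size=base.cell_size)
    suit_table = suitability_area_table(atlas, valid_mask=base.valid_mask)
    suit_table.to_csv(out / "suitability_structure.csv")

    # --- stages 3–4: hindcast validation ------------------------------------
    _stage("hindcast")
    hindcast = validate_hindcast(
        series, atlas, n_iterations=config.iterations_hindcast, seed=config.seed
    )

    # --- stage 5: horizon prediction (scenario 1) ---------------------------
    _stage("predict")
    overall = cross_tabulate(series[0], series[-1])
    demand_s1 = markov_project(
        overall.probabilities, area_vector(base), config.horizon_periods
    )
    scenario_1 = ca_allocate(
        base, demand_s1, atlas,
        n_iterations=config.iterations_forecast, seed=config.seed,
    )
    write_grid(out / "scenario_1.tif", scenario_1)

    # --- stage 6: optimization (scenario 2) ---------------------------------
    _stage("optimize")
    areas = class_areas(base).set_index("class_label")["area_km2"]
    # benefit coefficients: documented placeholders favouring forest/water
    eco = {"FL": 1.0, "SL": 0.8, "GL": 0.6, "WB": 0.9, "CL": 0.3, "OC": 0.4,
           "WL": 0.2, "BL": 0.0, "BUL": 0.0}
    econ = {"BUL": 1.0, "OC": 0.6, "CL": 0.5, "FL": 0.3, "SL": 0.2, "GL": 0.2,
            "WB": 0.3, "WL": 0.0, "BL": 0.0}
    slack = 0.1
    lp = StructureLP(
        total_area=float(areas.sum()),
        eco_benefit=eco, econ_benefit=econ,
        lower={l: areas[l] * (1 - slack) for l in areas.index},
        upper={l: areas[l] * (1 + slack) for l in areas.index},
    )
    demand_s2 = solve_structure(lp)
    scenario_2 = priority_allocate(base, demand_s2, atlas, seed=config.seed)
    write_grid(out / "scenario_2.tif", scenario_2)

    # --- stage 7: ecosystem services + comparison ---------------------------
    _stage("services")
    wy_params, er_params = WaterYieldParams(), ErosionParams()
    totals = {}
    for name, grid in [("base", base), ("scenario_1", scenario_1), ("scenario_2", scenario_2)]:
        totals[name] = assess_all(stack, grid, wy_params, er_params).totals
    totals_table = pd.DataFrame(totals)
    totals_table.to_csv(out / "es_totals.csv")
    changes = compare_scenarios(totals_table, base="base")
    changes.to_csv(out / "es_changes.csv", index=False)

    comp = pd.DataFrame({
        "base": class_areas(base).set_index("class_label")["area_km2"],
        "scenario_1": class_areas(scenario_1).set_index("class_label")["area_km2"],
        "scenario_2": class_areas(scenario_2).set_index("class_label")["area_km2"],
    })
    comp.to_csv(out / "compositions.csv")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "shape": list(config.shape),
        "cell_size": config.cell_size,
        "n_dates": config.n_dates,
        "iterations": [config.iterations_hindcast, config.iterations_forecast],
        "hindcast_kappa": hindcast.overall.kappa,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "series": series,
        "atlas": atlas,
        "hindcast": hindcast,
        "scenario_1": scenario_1,
        "scenario_2": scenario_2,
        "metrics": metrics_table,
        "suitability": suit_table,
        "es_totals": totals_table,
        "es_changes": changes,
        "compositions": comp,
        "manifest": manifest,
    }
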