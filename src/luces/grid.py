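"""Raster data model shared by every pipeline stage.

Two kinds of single-band raster are supported:

* categorical land-cover grids on a fixed 9-class legend
  (cropland CL, orchard OC, forestland FL, shrubland SL, grassland GL,
  bareland BL, waterbodies WB, wasteland WL, built-up BUL), and
* continuous surfaces (DEM, climate, soils) bundled into a
  :class:`RasterStack`.

Grids are abstract aligned arrays: row 0 is north, indices are 0-based,
no projection metadata is carried.  File formats are single-band TIFF
(metadata in the ImageDescription tag) and the ESRI ASCII grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Fixed class legend: code -> label.
LEGEND: dict[int, str] = {
    1: "CL",   # cropland
    2: "OC",   # orchard
    3: "FL",   # forestland
    4: "SL",   # shrubland
    5: "GL",   # grassland
    6: "BL",   # bareland
    7: "WB",   # waterbodies
    8: "WL",   # wasteland
    9: "BUL",  # built-up land
}

#: label -> code, the inverse of :data:`LEGEND`.
CODES: dict[str, int] = {v: k for k, v in LEGEND.items()}

CLASS_CODES = tuple(LEGEND)

DEFAULT_CELL_SIZE = 30.0
DEFAULT_NODATA = -9999

#: Sentinel aspect value for flat cells (slope 0, aspect undefined).
FLAT_ASPECT = -1.0


class GridError(ValueError):
    """Raised for malformed rasters, unknown class codes or misalignment."""


@dataclass
class LandCoverGrid:
    """Categorical land-cover raster on the 9-class legend.

    Parameters
    ----------
    values
        2-D integer array of class codes; ``nodata`` marks invalid cells.
    cell_size
        Cell edge length in metres.
    nodata
        Reserved integer code for invalid cells.
    """

    values: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE
    nodata: int = DEFAULT_NODATA
    legend: dict[int, str] = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GridError(f"land-cover grid must be 2-D, got {self.values.ndim}-D")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise GridError("land-cover grid must hold integer class codes")
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")
        self.validate_legend()

    def validate_legend(self) -> None:
        mask = self.values != self.nodata
        bad = ~np.isin(self.values, list(self.legend)) & mask
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise GridError(
                f"unknown class code {int(self.values[idx])} at cell {idx}; "
                f"legend codes are {sorted(self.legend)}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6

    def class_counts(self) -> dict[int, int]:
        """Cell count per legend code (zero for absent classes)."""
        vals = self.values[self.valid_mask]
        counts = dict.fromkeys(self.legend, 0)
        codes, n = np.unique(vals, return_counts=True)
        counts.update({int(c): int(k) for c, k in zip(codes, n)})
        return counts

    def copy(self) -> "LandCoverGrid":
        return LandCoverGrid(
            self.values.copy(), self.cell_size, self.nodata, dict(self.legend)
        )


@dataclass
class Raster:
    """Continuous single-band raster; NaN marks nodata."""

    values: np.ndarray
    cell_size: float = DEFAULT_CELL_SIZE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridError(f"raster must be 2-D, got {self.values.ndim}-D")
        if self.cell_size <= 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


class RasterStack:
    """Named, co-registered continuous rasters sharing shape and cell size.

    Conventional layer names: ``dem`` (m), ``slope`` (degrees), ``aspect``
    (degrees, :data:`FLAT_ASPECT` for flat cells), ``precipitation`` (mm/yr),
    ``et0`` (reference evapotranspiration, mm/yr), ``awc`` (plant-available
    water content, mm), ``erosivity`` (R), ``erodibility`` (K), ``ph``.
    """

    def __init__(self, layers: dict[str, Raster] | None = None) -> None:
        self._layers: dict[str, Raster] = {}
        for name, raster in (layers or {}).items():
            self.add(name, raster)

    def add(self, name: str, raster: Raster) -> None:
        if self._layers:
            ref = next(iter(self._layers.values()))
            if raster.shape != ref.shape:
                raise GridError(
                    f"layer {name!r} shape {raster.shape} != stack shape {ref.shape}"
                )
            if not math.isclose(raster.cell_size, ref.cell_size):
                raise GridError(
                    f"layer {name!r} cell size {raster.cell_size} != {ref.cell_size}"
                )
        self._layers[name] = raster

    def __getitem__(self, name: str) -> Raster:
        return self._layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._layers.values())).shape

    @property
    def cell_size(self) -> float:
        return next(iter(self._layers.values())).cell_size


def check_aligned(a, b) -> None:
    """Raise :class:`GridError` unless two grids share shape and cell size."""
    if a.shape != b.shape:
        raise GridError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not math.isclose(a.cell_size, b.cell_size):
        raise GridError(f"cell size mismatch: {a.cell_size} vs {b.cell_size}")


# ---------------------------------------------------------------------------
# I/O: ESRI ASCII grid and single-band TIFF
# ---------------------------------------------------------------------------

_ASC_SUFFIXES = {".asc", ".txt"}
_TIF_SUFFIXES = {".tif", ".tiff"}


def _read_ascii(path: Path) -> tuple[np.ndarray, float, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridError(f"{path}: ESRI ASCII header missing {key}")
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridError(
            f"{path}: body shape {body.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return body, header["cellsize"], header.get("nodata_value", DEFAULT_NODATA)


def _write_ascii(path: Path, values: np.ndarray, cell_size: float, nodata) -> None:
    rows, cols = values.shape
    is_int = np.issubdtype(values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell_size:g}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, values, fmt="%d" if is_int else "%.10g")


def _read_tiff(path: Path) -> tuple[np.ndarray, float, float | None]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    if arr.ndim == 3:
        if arr.shape[-1] != 1 and arr.shape[0] != 1:
            raise GridError(f"{path}: multi-band rasters are not supported")
        arr = arr.reshape(sorted(arr.shape)[-2:]) if 1 in arr.shape else arr
        arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise GridError(f"{path}: expected a single-band 2-D raster")
    cell_size = float(meta.get("cell_size", DEFAULT_CELL_SIZE))
    nodata = meta.get("nodata")
    return arr, cell_size, nodata


def _write_tiff(path: Path, values: np.ndarray, cell_size: float, nodata) -> None:
    meta = {"cell_size": cell_size}
    if nodata is not None and not (isinstance(nodata, float) and math.isnan(nodata)):
        meta["nodata"] = nodata
    tifffile.imwrite(path, values, description=json.dumps(meta))


def read_grid(path, expected_kind: str = "landcover", cell_size: float | None = None):
    """Read a raster, validating it against the expected kind.

    Parameters
    ----------
    path
        File path; ``.asc``/``.txt`` is parsed as ESRI ASCII, ``.tif``/``.tiff``
        as single-band TIFF.
    expected_kind
        ``"landcover"`` returns a :class:`LandCoverGrid` validated against the
        legend; ``"continuous"`` returns a :class:`Raster` with nodata mapped
        to NaN.
    cell_size
        Override for formats whose metadata lacks one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in _ASC_SUFFIXES:
        values, size, nodata = _read_ascii(path)
    elif suffix in _TIF_SUFFIXES:
        values, size, nodata = _read_tiff(path)
    else:
        raise GridError(f"{path}: unsupported raster format {suffix!r}")
    if cell_size is not None:
        size = cell_size
    if expected_kind == "landcover":
        ivals = values.astype(np.int64)
        if not np.array_equal(ivals, values):
            raise GridError(f"{path}: categorical raster holds non-integer values")
        nd = int(nodata) if nodata is not None else DEFAULT_NODATA
        return LandCoverGrid(ivals, cell_size=size, nodata=nd)
    if expected_kind == "continuous":
        fvals = values.astype(float)
        if nodata is not None:
            fvals[fvals == float(nodata)] = np.nan
        return Raster(fvals, cell_size=size)
    raise ValueError(f"expected_kind must be 'landcover' or 'continuous', got {expected_kind!r}")


def write_grid(path, grid: LandCoverGrid | Raster) -> None:
    """Write a grid to ESRI ASCII or TIFF, chosen by file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if isinstance(grid, LandCoverGrid):
        values, nodata = grid.values, grid.nodata
    else:
        nodata = DEFAULT_NODATA
        values = np.where(np.isnan(grid.values), float(nodata), grid.values)
    if suffix in _ASC_SUFFIXES:
        _write_ascii(path, values, grid.cell_size, nodata)
    elif suffix in _TIF_SUFFIXES:
        _write_tiff(path, values, grid.cell_size, nodata)
    else:
        raise GridError(f"{path}: unsupported raster format {suffix!r}")


# ---------------------------------------------------------------------------
# Class-area accounting
# ---------------------------------------------------------------------------

def class_areas(grid: LandCoverGrid) -> pd.DataFrame:
    """Per-class areas in km².

    ``area_c = count_c * cell_size**2 / 1e6``; nodata cells contribute
    nothing, so the column sum equals the valid area exactly.
    """
    counts = grid.class_counts()
    return pd.DataFrame(
        {
            "class_code": list(grid.legend),
            "class_label": [grid.legend[c] for c in grid.legend],
            "area_km2": [counts[c] * grid.cell_area_km2 for c in grid.legend],
        }
    )


def area_vector(grid: LandCoverGrid) -> np.ndarray:
    """Areas (km²) as a length-9 vector in legend order."""
    return class_areas(grid)["area_km2"].to_numpy()
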