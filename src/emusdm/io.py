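"""File formats: ESRI ASCII rasters + JSON sidecars, occurrence CSV, reports.

Rasters are written as single-band ESRI ASCII grids (.asc) — a plain-text
georeferenced format readable by every GIS — one file per layer, with a
JSON sidecar carrying the layer names, cell size, CRS tag and provenance
(config hash, stage, seed).  Row 0 is the northernmost row, matching the
in-memory convention; nodata round-trips as NaN.  Values survive a
round-trip to float32 precision or better (we print with repr precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid, GridSurface, PredictorStack
from .synthetic import OCCURRENCE_COLUMNS

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_stack",
    "read_stack",
    "write_occurrences",
    "read_occurrences",
    "write_json",
    "read_json",
    "config_hash",
]

NODATA = -9999.0


def write_ascii_grid(path: str | Path, surface: GridSurface) -> None:
    grid = surface.grid
    vals = np.where(np.isfinite(surface.values), surface.values, NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {float(grid.x_origin_km):.17g}\n"
        f"yllcorner {float(grid.y_origin_km):.17g}\n"
        f"cellsize {float(grid.cell_size_km):.17g}\n"
        f"NODATA_value {NODATA:.17g}\n"
    )
    # 9 significant digits: exceeds float32 fidelity, keeps files compact
    body = "\n".join(" ".join(f"{float(v):.9g}" for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, crs: str = "planar_km") -> GridSurface:
    lines = Path(path).read_text().splitlines()
    meta = {}
    for line in lines[:6]:
        key, val = line.split(None, 1)
        meta[key.lower()] = float(val)
    vals = np.loadtxt(lines[6:], dtype=float, ndmin=2)
    grid = Grid(
        n_rows=int(meta["nrows"]),
        n_cols=int(meta["ncols"]),
        cell_size_km=meta["cellsize"],
        x_origin_km=meta["xllcorner"],
        y_origin_km=meta["yllcorner"],
        crs=crs,
    )
    nodata = meta.get("nodata_value", NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return GridSurface(grid, vals)


def write_stack(directory: str | Path, stack: PredictorStack, provenance: dict | None = None) -> None:
    """One .asc per layer plus a stack.json sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.items():
        write_ascii_grid(directory / f"{name}.asc", GridSurface(stack.grid, arr))
    sidecar = {
        "layer_names": stack.names,
        "n_rows": stack.grid.n_rows,
        "n_cols": stack.grid.n_cols,
        "cell_size_km": stack.grid.cell_size_km,
        "x_origin_km": stack.grid.x_origin_km,
        "y_origin_km": stack.grid.y_origin_km,
        "crs": stack.grid.crs,
        "provenance": provenance or {},
    }
    write_json(directory / "stack.json", sidecar)


def read_stack(directory: str | Path) -> PredictorStack:
    directory = Path(directory)
    sidecar = read_json(directory / "stack.json")
    layers = {}
    ref_grid: Grid | None = None
    for name in sidecar["layer_names"]:
        surf = read_ascii_grid(directory / f"{name}.asc", crs=sidecar.get("crs", "planar_km"))
        if ref_grid is None:
            ref_grid = surf.grid
        elif not ref_grid.same_grid(surf.grid):
            raise ValueError(f"layer {name!r} grid mismatches the stack grid")
        layers[name] = surf.values
    assert ref_grid is not None
    return PredictorStack(ref_grid, layers)


def write_occurrences(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV lacks columns: {missing}")
    for c in ("is_fossil", "is_absence_record"):
        df[c] = df[c].astype(bool)
    # extra columns pass through untouched
    return df


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a config mapping, for provenance stamps."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
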