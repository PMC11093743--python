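"""Plain-text file formats: CSV tables, GeoJSON coastlines, ESRI ASCII grids.

All tabular data are CSV with ISO 8601 dates (UTC); schema violations are
reported with 1-based file line numbers (header = line 1).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .morphometry import LEVELS
from .topography import BathymetryGrid, Coastline

__all__ = [
    "read_sea_state_csv",
    "write_sea_state_csv",
    "read_barnacle_csv",
    "write_barnacle_csv",
    "read_inshore_csv",
    "write_inshore_csv",
    "read_coastline_geojson",
    "write_coastline_geojson",
    "read_ascii_grid",
    "write_ascii_grid",
    "write_json_report",
]

SEA_STATE_COLUMNS = ["timestamp", "point_id", "Hs_m", "Tp_s", "dir_deg"]
BARNACLE_COLUMNS = ["site_id", "date", "level", "TL_mm", "DBC_mm"]
INSHORE_COLUMNS = ["date", "point_id", "H_i_max", "u_i_max"]


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _bad_lines(mask: np.ndarray) -> str:
    # +2: 1-based and header line
    lines = (np.flatnonzero(mask) + 2).tolist()
    shown = ", ".join(map(str, lines[:10]))
    more = f" (+{len(lines) - 10} more)" if len(lines) > 10 else ""
    return shown + more


def read_sea_state_csv(path) -> pd.DataFrame:
    """Read an hourly sea-state CSV (timestamp, point_id, Hs_m, Tp_s, dir_deg)."""
    df = pd.read_csv(path, dtype={"point_id": str})
    _require_columns(df, SEA_STATE_COLUMNS, path)
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable timestamp ({exc})") from exc
    for col, lo, hi in [("Hs_m", 0.0, np.inf), ("Tp_s", 1e-9, np.inf), ("dir_deg", 0.0, 360.0)]:
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | (v < lo) | (v >= hi) if col == "dir_deg" else v.isna() | (v < lo)
        if bad.any():
            raise SchemaError(f"{path}: invalid {col} at line(s) {_bad_lines(bad.to_numpy())}")
        df[col] = v
    return df[SEA_STATE_COLUMNS]


def write_sea_state_csv(df: pd.DataFrame, path) -> None:
    out = df[SEA_STATE_COLUMNS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    out.to_csv(path, index=False)


def read_barnacle_csv(path) -> pd.DataFrame:
    """Read barnacle records (site_id, date, level, TL_mm, DBC_mm)."""
    df = pd.read_csv(path, dtype={"site_id": str, "level": str})
    _require_columns(df, BARNACLE_COLUMNS, path)
    try:
        df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{path}: unparseable date ({exc})") from exc
    bad = ~df["level"].isin(LEVELS)
    if bad.any():
        raise SchemaError(
            f"{path}: unknown intertidal level at line(s) {_bad_lines(bad.to_numpy())} "
            f"(expected one of {LEVELS})"
        )
    for col in ("TL_mm", "DBC_mm"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | (v <= 0)
        if bad.any():
            raise SchemaError(f"{path}: invalid {col} at line(s) {_bad_lines(bad.to_numpy())}")
        df[col] = v
    return df[BARNACLE_COLUMNS]


def write_barnacle_csv(df: pd.DataFrame, path) -> None:
    out = df[BARNACLE_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_inshore_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"point_id": str})
    _require_columns(df, INSHORE_COLUMNS, path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for col in ("H_i_max", "u_i_max"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = v.isna() | (v < 0)
        if bad.any():
            raise SchemaError(f"{path}: invalid {col} at line(s) {_bad_lines(bad.to_numpy())}")
        df[col] = v
    return df[INSHORE_COLUMNS]


def write_inshore_csv(df: pd.DataFrame, path) -> None:
    df[INSHORE_COLUMNS].to_csv(path, index=False)


def read_coastline_geojson(path) -> Coastline:
    """Read a GeoJSON LineString (bare geometry, Feature or FeatureCollection)."""
    with open(path) as fh:
        obj = json.load(fh)
    geom = obj
    if obj.get("type") == "FeatureCollection":
        geom = obj["features"][0]["geometry"]
    elif obj.get("type") == "Feature":
        geom = obj["geometry"]
    if geom.get("type") != "LineString":
        raise SchemaError(f"{path}: expected a LineString, got {geom.get('type')!r}")
    return Coastline(np.asarray(geom["coordinates"], float))


def write_coastline_geojson(coast: Coastline, path) -> None:
    obj = {
        "type": "Feature",
        "properties": {},
        "geometry": {
            "type": "LineString",
            "coordinates": [[float(x), float(y)] for x, y in coast.vertices],
        },
    }
    with open(path, "w") as fh:
        json.dump(obj, fh)


def read_ascii_grid(path) -> BathymetryGrid:
    """Read an ESRI ASCII raster of depths (m, positive down)."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise SchemaError(f"{path}: missing ASCII-grid header field {key!r}")
    data = np.asarray(rows, float)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(
            f"{path}: grid body {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return BathymetryGrid(
        data=data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(grid: BathymetryGrid, path) -> None:
    nrows, ncols = grid.data.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.data:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_json_report(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))
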