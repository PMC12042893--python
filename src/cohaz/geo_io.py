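"""Reading/writing standard formats and spatial aggregation to tracts.

Tract polygons travel as GeoJSON, daily fields as CF-style NetCDF
(dims ``time, y, x``), fire points and tabular outputs as CSV.  The two
aggregation primitives are :func:`zonal_mean` (area-weighted grid-cell
mean per tract-day) and :func:`points_to_counts` (daily point-in-polygon
counts with an explicit unassigned tally).

Area weights are computed on an equal-area representation: geographic
coordinates (EPSG:4326) go through a sinusoidal projection; the
``"planar"`` CRS used by toy fixtures is taken as already equal-area.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Point, box, mapping, shape
from shapely.ops import transform as shp_transform
from shapely.strtree import STRtree

from .containers import (
    TRACT_COLUMNS,
    DailyField,
    FirePointSet,
    TractDayMatrix,
    TractTable,
    ValidationError,
)

EARTH_RADIUS_M = 6_371_008.8


# ---------------------------------------------------------------------------
# equal-area support

def _sinusoidal(lon, lat):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return (
        np.radians(lon) * EARTH_RADIUS_M * np.cos(np.radians(lat)),
        np.radians(lat) * EARTH_RADIUS_M,
    )


def equal_area_geometry(geom, crs: str):
    """Map a geometry to an equal-area plane for area computation."""
    if crs == "planar":
        return geom
    if crs.upper() in ("EPSG:4326", "WGS84", "OGC:CRS84"):
        return shp_transform(_sinusoidal, geom)
    raise ValidationError(f"unsupported CRS {crs!r}")


# ---------------------------------------------------------------------------
# tract I/O

def write_tracts(tracts: TractTable, path: str | Path) -> None:
    """Write a TractTable as a GeoJSON FeatureCollection."""
    features = []
    for _, row in tracts.data.iterrows():
        props = {c: row[c] for c in TRACT_COLUMNS}
        props["svi"] = None if pd.isna(row["svi"]) else float(row["svi"])
        props["tribal_overlap"] = bool(row["tribal_overlap"])
        props["coastal"] = bool(row["coastal"])
        features.append({
            "type": "Feature",
            "geometry": mapping(row["geometry"]),
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "crs_name": tracts.crs,
           "features": features}
    Path(path).write_text(json.dumps(doc))


def read_tracts(path: str | Path) -> TractTable:
    """Read tract polygons + attributes from GeoJSON.

    A missing ``crs_name`` member defaults to EPSG:4326 (the GeoJSON
    convention).  Duplicate tract ids and malformed features raise with
    the offending feature index / tract_id in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    crs = doc.get("crs_name", "EPSG:4326")
    rows = []
    for i, feat in enumerate(doc.get("features", [])):
        try:
            geom = shape(feat["geometry"])
            props = dict(feat["properties"])
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"malformed GeoJSON feature at index {i}: {exc}")
        missing = [c for c in TRACT_COLUMNS if c not in props]
        if missing:
            raise ValidationError(
                f"feature {i} (tract_id={props.get('tract_id')!r}) "
                f"missing properties {missing}"
            )
        props["svi"] = np.nan if props["svi"] is None else float(props["svi"])
        props["geometry"] = geom
        rows.append(props)
    data = pd.DataFrame(rows)
    return TractTable(data, crs=crs)


# ---------------------------------------------------------------------------
# field I/O (CF-style NetCDF via the scipy backend)

def write_field(field: DailyField, path: str | Path) -> None:
    da = xr.DataArray(
        field.values,
        dims=("time", "y", "x"),
        coords={
            "time": field.dates,
            "y": field.y_centers(),
            "x": field.x_centers(),
        },
        name=field.name,
        attrs={"units": field.units, "crs": field.crs},
    )
    da.to_dataset().to_netcdf(Path(path), engine="scipy")


def _edges_from_centers(centers: np.ndarray, axis: str) -> np.ndarray:
    centers = np.asarray(centers, dtype=float)
    if len(centers) == 1:
        raise ValidationError(f"cannot infer {axis} cell size from one center")
    steps = np.diff(centers)
    if not np.allclose(steps, steps[0]):
        raise ValidationError(f"non-uniform {axis} grid spacing")
    d = steps[0]
    return np.concatenate([centers - d / 2, [centers[-1] + d / 2]])


_TEMP_CONVERT = {
    "degc": lambda v: v, "c": lambda v: v, "celsius": lambda v: v,
    "k": lambda v: v - 273.15, "kelvin": lambda v: v - 273.15,
    "degf": lambda v: (v - 32.0) * 5.0 / 9.0, "f": lambda v: (v - 32.0) * 5.0 / 9.0,
}


def read_field(path: str | Path, var: str | None = None) -> DailyField:
    """Read a daily field from NetCDF; temperatures converted to degC.

    The variable's ``units`` attribute selects the conversion (K, degC
    or degF -> degC; anything else passes through).  A skipped calendar
    day raises a gap error; a missing ``crs`` attribute is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with xr.open_dataset(path, engine="scipy") as ds:
        if var is None:
            data_vars = list(ds.data_vars)
            if len(data_vars) != 1:
                raise ValidationError(
                    f"specify var=, file has data variables {data_vars}"
                )
            var = data_vars[0]
        da = ds[var].load()
    units = da.attrs.get("units", "")
    crs = da.attrs.get("crs")
    if crs is None:
        raise ValidationError(f"{path}: variable {var!r} has no crs attribute")
    values = np.asarray(da.values, dtype=float)
    key = units.lower().replace(" ", "")
    if key in _TEMP_CONVERT:
        values = _TEMP_CONVERT[key](values)
        units = "degC"
    dates = pd.DatetimeIndex(da["time"].values).normalize()
    return DailyField(
        values,
        dates,
        _edges_from_centers(da["x"].values, "x"),
        _edges_from_centers(da["y"].values, "y"),
        units=units,
        crs=crs,
        name=var,
    )


# ---------------------------------------------------------------------------
# fire points / tables / matrices

def write_fire_points(points: FirePointSet, path: str | Path) -> None:
    out = points.data.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_fire_points(path: str | Path) -> FirePointSet:
    """Read (date, lon, lat) CSV; bad rows raise with their line number."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype={"date": str})
    for col in ("date", "lon", "lat"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    dates = pd.to_datetime(raw["date"], format="%Y-%m-%d", errors="coerce")
    bad = np.flatnonzero(dates.isna().to_numpy())
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValidationError(
            f"{path}: unparseable date {raw['date'].iloc[bad[0]]!r} "
            f"on line {bad[0] + 2}"
        )
    out = raw.copy()
    out["date"] = dates
    return FirePointSet(out)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def write_matrix(matrix: TractDayMatrix, path: str | Path) -> None:
    frame = matrix.to_frame()
    frame.columns = frame.columns.strftime("%Y-%m-%d")
    frame.index.name = "tract_id"
    if matrix.is_boolean:
        frame = frame.astype(int)
    frame.to_csv(path)


def read_matrix(path: str | Path, boolean: bool = False,
                name: str = "value") -> TractDayMatrix:
    frame = pd.read_csv(path, index_col="tract_id", dtype={"tract_id": str})
    dates = pd.DatetimeIndex(pd.to_datetime(frame.columns))
    values = frame.to_numpy()
    if boolean:
        values = values.astype(bool)
    return TractDayMatrix(values, pd.Index(frame.index), dates, name=name)


# ---------------------------------------------------------------------------
# spatial aggregation

def zonal_mean(field: DailyField, tracts: TractTable) -> TractDayMatrix:
    """Area-weighted mean of intersecting grid cells, per tract-day.

    Weights are the equal-area intersection areas of each tract polygon
    with the rectilinear cells, normalised within the tract.  A tract
    that intersects no cell (zero total area) is an error.
    """
    if field.crs != tracts.crs:
        raise ValidationError(
            f"field CRS {field.crs!r} != tract CRS {tracts.crs!r}"
        )
    xe, ye = field.x_edges, field.y_edges
    n_days = len(field.dates)
    out = np.zeros((len(tracts), n_days))
    empty: list[str] = []
    for row, (tid, geom) in enumerate(zip(tracts.tract_ids, tracts.geometries)):
        minx, miny, maxx, maxy = geom.bounds
        i0 = max(int(np.searchsorted(xe, minx, side="right")) - 1, 0)
        i1 = min(int(np.searchsorted(xe, maxx, side="left")), len(xe) - 1)
        j0 = max(int(np.searchsorted(ye, miny, side="right")) - 1, 0)
        j1 = min(int(np.searchsorted(ye, maxy, side="left")), len(ye) - 1)
        weights, series = [], []
        for j in range(j0, j1):
            for i in range(i0, i1):
                cell = box(xe[i], ye[j], xe[i + 1], ye[j + 1])
                inter = geom.intersection(cell)
                if inter.is_empty:
                    continue
                area = equal_area_geometry(inter, tracts.crs).area
                if area <= 0:
                    continue
                weights.append(area)
                series.append(field.values[:, j, i])
        if not weights:
            empty.append(tid)
            continue
        w = np.asarray(weights)
        w /= w.sum()
        out[row] = np.einsum("c,ct->t", w, np.asarray(series))
    if empty:
        raise ValidationError(
            f"tracts with zero intersecting grid area: {empty}"
        )
    return TractDayMatrix(out, tracts.tract_ids, field.dates, name=field.name)


def points_to_counts(
    points: FirePointSet,
    tracts: TractTable,
    dates: pd.DatetimeIndex,
) -> tuple[TractDayMatrix, pd.Series]:
    """Daily fire-point counts per tract, plus the unassigned tally.

    Containment is closed (boundary points count); a point covered by
    several tracts — only possible on shared boundaries — goes to the
    lowest ``tract_id`` so every in-domain point is counted exactly
    once.  Points outside all tracts land in the returned per-date
    ``unassigned`` Series rather than being dropped.
    """
    dates = pd.DatetimeIndex(dates)
    pdates = pd.DatetimeIndex(points.data["date"]).normalize()
    outside = ~pdates.isin(dates)
    if outside.any():
        raise ValidationError(
            f"{int(outside.sum())} fire points dated outside the date axis "
            f"(first: {pdates[outside][0].date()})"
        )
    date_pos = pd.Series(np.arange(len(dates)), index=dates)
    counts = np.zeros((len(tracts), len(dates)), dtype=int)
    unassigned = pd.Series(0, index=dates, name="unassigned")

    geoms = list(tracts.geometries)
    tree = STRtree(geoms)
    ids = tracts.tract_ids.to_numpy()

    for (_, rec), t in zip(points.data.iterrows(), date_pos[pdates].to_numpy()):
        pt = Point(rec["lon"], rec["lat"])
        # covered_by keeps boundary points (closed containment)
        cand = tree.query(pt, predicate="covered_by")
        if len(cand) == 0:
            unassigned.iloc[int(t)] += 1
            continue
        row = cand[np.argmin(ids[cand])] if len(cand) > 1 else cand[0]
        counts[int(row), int(t)] += 1
    return (
        TractDayMatrix(counts, tracts.tract_ids, dates, name="fire_count"),
        unassigned,
    )
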