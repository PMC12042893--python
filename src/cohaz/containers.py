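"""Core in-memory containers shared across the pipeline.

The pipeline moves data through four containers:

``TractTable``
    Census-tract polygons with population and sociodemographic attributes
    (one row per tract, shapely geometry column).
``DailyField``
    A daily gridded surface (maximum temperature or wildfire-smoke PM2.5)
    on a rectilinear grid with an ISO date axis.
``FirePointSet``
    Daily active-fire detections as (date, lon, lat) point records.
``TractDayMatrix``
    A tract x day matrix of values or boolean flags — the common currency
    of classification, coexposure and metric stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

#: Columns every TractTable carries, in canonical order.
TRACT_COLUMNS = [
    "tract_id", "state", "county", "population",
    "hispanic", "nh_white", "nh_black", "nh_asian", "nh_aian", "nh_other",
    "svi", "pct_65plus", "pct_disability", "pct_poverty150",
    "tribal_overlap", "coastal",
]

RACE_GROUPS = ["hispanic", "nh_white", "nh_black", "nh_asian", "nh_aian", "nh_other"]

SHARE_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class TractTable:
    """Tract polygons plus attributes.

    ``data`` holds one row per tract with the columns in
    :data:`TRACT_COLUMNS` and a ``geometry`` column of shapely polygons.
    ``crs`` is either ``"EPSG:4326"`` (longitude/latitude degrees) or
    ``"planar"`` (abstract Cartesian coordinates, used by toy fixtures).

    Invariants: unique ``tract_id``; race/ethnicity shares sum to 1 for
    populated tracts; SVI is missing exactly on zero-population tracts.
    """

    data: pd.DataFrame
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        missing = [c for c in TRACT_COLUMNS + ["geometry"] if c not in self.data.columns]
        if missing:
            raise ValidationError(f"TractTable missing columns: {missing}")
        ids = self.data["tract_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValidationError(f"duplicate tract_id values: {dups}")
        if (self.data["population"] < 0).any():
            raise ValidationError("negative population")
        populated = self.data["population"] > 0
        share_sum = self.data.loc[populated, RACE_GROUPS].sum(axis=1)
        bad = share_sum[(share_sum - 1.0).abs() > SHARE_TOL]
        if len(bad):
            raise ValidationError(
                f"race/ethnicity shares do not sum to 1 for tracts "
                f"{self.data.loc[bad.index, 'tract_id'].tolist()}"
            )
        svi_missing = self.data["svi"].isna()
        if (svi_missing != ~populated).any():
            off = self.data.loc[svi_missing != ~populated, "tract_id"].tolist()
            raise ValidationError(
                f"svi must be missing iff population is zero; violated by {off}"
            )
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def tract_ids(self) -> pd.Index:
        return pd.Index(self.data["tract_id"])

    @property
    def geometries(self) -> np.ndarray:
        return self.data["geometry"].to_numpy()

    @property
    def population(self) -> pd.Series:
        return self.data.set_index("tract_id")["population"]

    def attribute(self, name: str) -> pd.Series:
        return self.data.set_index("tract_id")[name]

    def sorted_by_id(self) -> "TractTable":
        return TractTable(
            self.data.sort_values("tract_id").reset_index(drop=True), crs=self.crs
        )


def _check_daily(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValidationError("empty date axis")
    deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
    if len(deltas) and not (deltas == 1).all():
        gap = int(np.argmax(deltas != 1))
        raise ValidationError(
            f"date axis is not strictly daily: gap after {dates[gap].date()} "
            f"(next is {dates[gap + 1].date()})"
        )
    return dates


@dataclass
class DailyField:
    """A daily surface on a rectilinear grid.

    ``values`` has shape (time, y, x).  ``x_edges``/``y_edges`` give the
    cell boundaries (len nx+1 / ny+1, strictly increasing), so cell (j, i)
    spans ``[x_edges[i], x_edges[i+1]] x [y_edges[j], y_edges[j+1]]``.
    """

    values: np.ndarray
    dates: pd.DatetimeIndex
    x_edges: np.ndarray
    y_edges: np.ndarray
    units: str
    crs: str = "EPSG:4326"
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dates = _check_daily(self.dates)
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.y_edges = np.asarray(self.y_edges, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("DailyField values must be 3-D (time, y, x)")
        t, ny, nx = self.values.shape
        if t != len(self.dates):
            raise ValidationError(
                f"time length {t} != number of dates {len(self.dates)}"
            )
        if len(self.y_edges) != ny + 1 or len(self.x_edges) != nx + 1:
            raise ValidationError("edge arrays do not match grid shape")
        if (np.diff(self.x_edges) <= 0).any() or (np.diff(self.y_edges) <= 0).any():
            raise ValidationError("grid edges must be strictly increasing")
        if not np.isfinite(self.values).all():
            raise ValidationError("non-finite values in DailyField")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class FirePointSet:
    """Active-fire point detections: one row per (date, lon, lat)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("date", "lon", "lat"):
            if col not in self.data.columns:
                raise ValidationError(f"FirePointSet missing column {col!r}")
        self.data = self.data.reset_index(drop=True)
        self.data["date"] = pd.to_datetime(self.data["date"])

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class TractDayMatrix:
    """A tract x day matrix (real values or boolean flags).

    Rows follow ``tract_ids`` order; columns follow the daily ``dates``
    axis with no gaps.
    """

    values: np.ndarray
    tract_ids: pd.Index
    dates: pd.DatetimeIndex
    name: str = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.tract_ids = pd.Index(self.tract_ids)
        self.dates = _check_daily(self.dates)
        if self.values.shape != (len(self.tract_ids), len(self.dates)):
            raise ValidationError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.tract_ids)} tracts, {len(self.dates)} days)"
            )
        if self.tract_ids.duplicated().any():
            raise ValidationError("duplicate tract_ids in TractDayMatrix")

    @property
    def is_boolean(self) -> bool:
        return self.values.dtype == bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tract_ids, columns=self.dates)

    def sorted_by_id(self) -> "TractDayMatrix":
        order = np.argsort(self.tract_ids.to_numpy())
        return TractDayMatrix(
            self.values[order], self.tract_ids[order], self.dates, self.name
        )

    def years(self) -> np.ndarray:
        return self.dates.year.to_numpy()

    def aligned_with(self, other: "TractDayMatrix") -> bool:
        return bool(
            self.tract_ids.equals(other.tract_ids) and self.dates.equals(other.dates)
        )


def require_aligned(*matrices: TractDayMatrix) -> None:
    """Raise unless all matrices share tract order and date axis."""
    first = matrices[0]
    for m in matrices[1:]:
        if not first.aligned_with(m):
            raise ValidationError(
                f"matrices {first.name!r} and {m.name!r} have misaligned axes"
            )
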