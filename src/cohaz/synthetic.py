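"""Synthetic tract geographies and daily hazard fields.

Generates the inputs the exposure pipeline consumes — a rectangular
lattice of census-tract polygons with population/sociodemographic
attributes, a daily maximum-temperature surface, daily active-fire
points, and a daily wildfire-smoke PM2.5 surface — with the statistical
structure the analysis assumes:

* seasonal temperature cycle peaking in mid-July, with planted
  multi-day heat events on top of Gaussian noise;
* summer-clustered fire ignitions that burn for 1-7 consecutive days,
  each burn day emitting at least one fire point inside the tract;
* smoke surfaces that are zero-inflated in the background and spread
  beyond the burning tract with multiplicative decay per tract of
  Chebyshev distance (smoke reaches farther than the burn zone);
* tract population, race/ethnicity shares, poverty/age/disability
  percentages, and a social-vulnerability percentile rank with a small
  fraction of zero-population tracts whose rank is missing.

Every planted heat-event day and ignition burn day is recorded in a
truth ledger so downstream classification can be scored exactly.

A single RNG stream is derived from ``SimConfig.seed`` and consumed in
a fixed order (tracts -> temperature -> fires/smoke), so
:func:`simulate_bundle` is bit-reproducible.  The component functions
accept an explicit ``rng`` for stream sharing; called standalone they
seed a fresh stream from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from shapely.geometry import box

from .containers import (
    DailyField,
    FirePointSet,
    TractTable,
    TractDayMatrix,
    ValidationError,
)

# mid-July calendar peak of the seasonal cycle
PEAK_DOY = 196
WARM_SEASON_MONTHS = (5, 6, 7, 8, 9)
FIRE_SEASON_MONTHS = (6, 7, 8, 9)

# Western-US-flavoured race/ethnicity mix (region shares: ~30% Hispanic,
# ~50% NH white, 1.1% NH AIAN) used as the Dirichlet mean.
RACE_ALPHA_MEAN = np.array([0.300, 0.499, 0.040, 0.055, 0.011, 0.095])
RACE_CONCENTRATION = 30.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study region and its hazard fields.

    Defaults mirror the scale of the real analysis where one exists
    (15 calendar years, ~4000 people per tract); hazard rates are set so
    a tract-summer sees a couple of heat events and fires are rare but
    summer-clustered.
    """

    seed: int = 0
    n_tracts_x: int = 8
    n_tracts_y: int = 8
    years: tuple[int, ...] = tuple(range(2006, 2021))
    grid_cells_per_tract: int = 2      # cells per tract side (k^2 per tract)
    base_temp_c: float = 14.0
    seasonal_amplitude_c: float = 20.0
    noise_sd_c: float = 2.5
    heat_event_rate: float = 2.0       # expected events per tract-summer
    heat_event_excess_c: float = 6.0
    fire_ignition_rate: float = 0.8    # expected ignitions per tract-year
    fire_summer_weight: float = 0.85   # fraction of ignitions in Jun-Sep
    smoke_plume_radius: int = 2        # tracts (Chebyshev)
    smoke_decay: float = 0.5           # per tract of distance
    smoke_source_ugm3: float = 20.0
    smoke_background_zero_prob: float = 0.95
    population_mean: float = 4000.0
    zero_population_frac: float = 0.003
    n_states: int = 3
    tract_size_deg: float = 0.1
    origin_lon: float = -113.0
    origin_lat: float = 38.0

    def __post_init__(self) -> None:
        if self.n_tracts_x < 2 or self.n_tracts_y < 2:
            raise ValidationError("tract lattice must be at least 2x2")
        if len(self.years) < 1:
            raise ValidationError("need at least one study year")
        ys = list(self.years)
        if ys != sorted(ys) or (len(ys) > 1 and np.any(np.diff(ys) != 1)):
            raise ValidationError("years must be consecutive ascending")
        for name in ("heat_event_rate", "fire_ignition_rate", "noise_sd_c",
                     "population_mean", "zero_population_frac",
                     "smoke_source_ugm3"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("fire_summer_weight", "smoke_background_zero_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0.0 < self.smoke_decay < 1.0:
            raise ValidationError("smoke_decay must be in (0, 1)")
        if self.grid_cells_per_tract < 1:
            raise ValidationError("grid_cells_per_tract must be >= 1")
        if self.smoke_plume_radius < 0:
            raise ValidationError("smoke_plume_radius must be >= 0")
        if self.n_states < 2:
            raise ValidationError("need at least 2 pseudo-states")

    def dates(self) -> pd.DatetimeIndex:
        """Daily calendar covering the study years (leap days included)."""
        return pd.date_range(
            f"{self.years[0]}-01-01", f"{self.years[-1]}-12-31", freq="D"
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        return d


@dataclass
class SyntheticBundle:
    """Everything one simulated study needs, plus the planted-event truth.

    ``truth`` has columns (tract_id, date, event) with event in
    {"heat", "fire"}; one row per planted tract-day.
    """

    config: SimConfig
    tracts: TractTable
    temperature: DailyField
    fire_points: FirePointSet
    smoke: DailyField
    truth: pd.DataFrame


def _lattice_geometry(config: SimConfig):
    """Row-major (iy, ix) square tract polygons and their index grids."""
    s = config.tract_size_deg
    iy, ix = np.mgrid[0:config.n_tracts_y, 0:config.n_tracts_x]
    iy, ix = iy.ravel(), ix.ravel()
    geoms = [
        box(
            config.origin_lon + x * s,
            config.origin_lat + y * s,
            config.origin_lon + (x + 1) * s,
            config.origin_lat + (y + 1) * s,
        )
        for y, x in zip(iy, ix)
    ]
    return iy, ix, geoms


def _state_of_column(ix: np.ndarray, config: SimConfig) -> np.ndarray:
    """Partition lattice columns into contiguous pseudo-states."""
    bounds = np.linspace(0, config.n_tracts_x, config.n_states + 1)
    state_idx = np.searchsorted(bounds, ix, side="right") - 1
    state_idx = np.clip(state_idx, 0, config.n_states - 1)
    return np.array([f"ST{i + 1:02d}" for i in state_idx])


def simulate_tracts(config: SimConfig, rng: np.random.Generator | None = None) -> TractTable:
    """Simulate the tract lattice with population and sociodemographics.

    Tracts tile an ``n_tracts_x x n_tracts_y`` rectangle of square
    polygons.  SVI is the percentile rank ``(rank-1)/(n-1)`` of a latent
    vulnerability score over populated tracts (rank ties broken by
    draw order), missing on zero-population tracts, mirroring how the
    CDC ranking drops zero-population tracts.  A contiguous block of
    tracts is flagged as overlapping tribal lands and the westernmost
    column as coastal.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    iy, ix, geoms = _lattice_geometry(config)
    n = len(geoms)
    state = _state_of_column(ix, config)
    # county blocks: pairs of lattice rows within each state
    county = np.array([f"C{y // 2 + 1:03d}" for y in iy])
    tract_id = np.array([
        f"{int(s[2:]):02d}{int(c[1:]):03d}{y * config.n_tracts_x + x:06d}"
        for s, c, y, x in zip(state, county, iy, ix)
    ])

    population = rng.poisson(config.population_mean, size=n).astype(float)
    zero_mask = rng.random(n) < config.zero_population_frac
    population[zero_mask] = 0.0

    shares = rng.dirichlet(RACE_ALPHA_MEAN * RACE_CONCENTRATION, size=n)

    pct_poverty150 = np.clip(rng.normal(20.9, 8.0, n), 0.5, 95.0)
    pct_65plus = np.clip(rng.normal(16.0, 6.0, n), 1.0, 60.0)
    pct_disability = np.clip(rng.normal(12.7, 5.0, n), 0.5, 50.0)

    # latent vulnerability drives the SVI rank; tied to poverty and
    # disability so disparity analyses have signal to find
    latent = (
        (pct_poverty150 - pct_poverty150.mean()) / pct_poverty150.std()
        + 0.5 * (pct_disability - pct_disability.mean()) / pct_disability.std()
        + rng.normal(0.0, 0.5, n)
    )
    svi = np.full(n, np.nan)
    populated = population > 0
    n_pop = int(populated.sum())
    if n_pop >= 2:
        order = np.argsort(latent[populated], kind="stable")
        ranks = np.empty(n_pop)
        ranks[order] = np.arange(n_pop)
        svi[populated] = ranks / (n_pop - 1)
    elif n_pop == 1:
        svi[populated] = 1.0

    # contiguous tribal block of roughly a quarter of the lattice extent
    bw = max(1, config.n_tracts_x // 4)
    bh = max(1, config.n_tracts_y // 4)
    bx = int(rng.integers(0, config.n_tracts_x - bw + 1))
    by = int(rng.integers(0, config.n_tracts_y - bh + 1))
    tribal = (ix >= bx) & (ix < bx + bw) & (iy >= by) & (iy < by + bh)

    data = pd.DataFrame({
        "tract_id": tract_id,
        "state": state,
        "county": county,
        "population": population,
        "hispanic": shares[:, 0],
        "nh_white": shares[:, 1],
        "nh_black": shares[:, 2],
        "nh_asian": shares[:, 3],
        "nh_aian": shares[:, 4],
        "nh_other": shares[:, 5],
        "svi": svi,
        "pct_65plus": pct_65plus,
        "pct_disability": pct_disability,
        "pct_poverty150": pct_poverty150,
        "tribal_overlap": tribal,
        "coastal": ix == 0,
        "geometry": geoms,
    })
    return TractTable(data, crs="EPSG:4326")


def seasonal_tmax(dates: pd.DatetimeIndex, config: SimConfig) -> np.ndarray:
    """Noise-free seasonal daily maximum temperature (degC)."""
    doy = dates.dayofyear.to_numpy()
    return config.base_temp_c + config.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (doy - PEAK_DOY) / 365.25
    )


def _grid_edges(config: SimConfig):
    k = config.grid_cells_per_tract
    s = config.tract_size_deg
    x_edges = config.origin_lon + s / k * np.arange(config.n_tracts_x * k + 1)
    y_edges = config.origin_lat + s / k * np.arange(config.n_tracts_y * k + 1)
    return x_edges, y_edges


def _tract_cell_slices(config: SimConfig, row: int):
    """Grid-cell slice of tract at row-major index ``row``."""
    k = config.grid_cells_per_tract
    iy, ix = divmod(row, config.n_tracts_x)
    return slice(iy * k, (iy + 1) * k), slice(ix * k, (ix + 1) * k)


def simulate_temperature(
    config: SimConfig,
    tracts: TractTable,
    rng: np.random.Generator | None = None,
) -> tuple[DailyField, pd.DataFrame]:
    """Simulate the daily maximum-temperature surface with planted heat events.

    Each cell's series is the seasonal sinusoid plus i.i.d. Gaussian
    noise.  Per tract and warm season (May-Sep), a Poisson number of
    heat events is planted; each adds ``heat_event_excess_c`` to every
    cell of the tract for 1-5 consecutive days.  Returns the field and
    the truth ledger of planted (tract_id, date, "heat") rows.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dates = config.dates()
    x_edges, y_edges = _grid_edges(config)
    ny, nx = len(y_edges) - 1, len(x_edges) - 1

    base = seasonal_tmax(dates, config)
    values = np.broadcast_to(base[:, None, None], (len(dates), ny, nx)).copy()
    if config.noise_sd_c > 0:
        values += rng.normal(0.0, config.noise_sd_c, size=values.shape)

    warm = np.flatnonzero(dates.month.isin(WARM_SEASON_MONTHS))
    warm_by_year: dict[int, np.ndarray] = {}
    for y in config.years:
        warm_by_year[y] = warm[dates.year[warm] == y]

    truth_rows = []
    date_pos = pd.Series(np.arange(len(dates)), index=dates)
    for row, tid in enumerate(tracts.tract_ids):
        ys_sl, xs_sl = _tract_cell_slices(config, row)
        for year in config.years:
            pool = warm_by_year[year]
            n_events = rng.poisson(config.heat_event_rate)
            for _ in range(n_events):
                start = int(rng.choice(pool))
                duration = int(rng.integers(1, 6))
                stop = min(start + duration, len(dates))
                values[start:stop, ys_sl, xs_sl] += config.heat_event_excess_c
                for t in range(start, stop):
                    truth_rows.append((tid, dates[t], "heat"))

    field = DailyField(values, dates, x_edges, y_edges, units="degC",
                       crs=tracts.crs, name="tmax")
    truth = pd.DataFrame(truth_rows, columns=["tract_id", "date", "event"])
    truth = truth.drop_duplicates().reset_index(drop=True)
    return field, truth


def simulate_fires_and_smoke(
    config: SimConfig,
    tracts: TractTable,
    rng: np.random.Generator | None = None,
) -> tuple[FirePointSet, DailyField, pd.DataFrame]:
    """Simulate ignitions, their fire points, and the smoke surface.

    Ignitions per tract-year are Poisson with ``fire_summer_weight`` of
    the mass placed in June-September.  Each ignition burns 1-7
    consecutive days and drops ``1 + Poisson(1)`` fire points uniformly
    inside the tract on every burn day.  On burn days the source tract
    receives ``smoke_source_ugm3`` of smoke, decayed by ``smoke_decay``
    per tract of Chebyshev distance out to ``smoke_plume_radius``;
    contributions from simultaneous fires add.  A zero-inflated
    exponential background (mean 1 ug/m3, nonzero with probability
    ``1 - smoke_background_zero_prob``) is added per tract-day.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dates = config.dates()
    n_days = len(dates)
    n = len(tracts)
    nyx = (config.n_tracts_y, config.n_tracts_x)

    fire_idx = np.flatnonzero(dates.month.isin(FIRE_SEASON_MONTHS))
    off_idx = np.flatnonzero(~dates.month.isin(FIRE_SEASON_MONTHS))

    smoke_tract = np.zeros((n, n_days))
    point_rows = []
    truth_rows = []

    iy_all = np.arange(n) // config.n_tracts_x
    ix_all = np.arange(n) % config.n_tracts_x
    # precomputed plume kernel per source tract: rows within Chebyshev radius
    radius, decay, amp = (config.smoke_plume_radius, config.smoke_decay,
                          config.smoke_source_ugm3)

    for row, tid in enumerate(tracts.tract_ids):
        geom = tracts.geometries[row]
        minx, miny, maxx, maxy = geom.bounds
        cheb = np.maximum(np.abs(iy_all - iy_all[row]),
                          np.abs(ix_all - ix_all[row]))
        in_plume = np.flatnonzero(cheb <= radius)
        plume_w = amp * decay ** cheb[in_plume]
        for year in config.years:
            n_ign = rng.poisson(config.fire_ignition_rate)
            for _ in range(n_ign):
                summer = rng.random() < config.fire_summer_weight
                pool = fire_idx if summer else off_idx
                pool = pool[dates.year[pool] == year]
                if len(pool) == 0:
                    pool = np.flatnonzero(dates.year == year)
                start = int(rng.choice(pool))
                duration = int(rng.integers(1, 8))
                stop = min(start + duration, n_days)
                for t in range(start, stop):
                    n_pts = 1 + int(rng.poisson(1.0))
                    lons = rng.uniform(minx, maxx, n_pts)
                    lats = rng.uniform(miny, maxy, n_pts)
                    for lon, lat in zip(lons, lats):
                        point_rows.append((dates[t], lon, lat))
                    smoke_tract[in_plume, t] += plume_w
                    truth_rows.append((tid, dates[t], "fire"))

    background = rng.exponential(1.0, size=smoke_tract.shape)
    keep = rng.random(smoke_tract.shape) >= config.smoke_background_zero_prob
    smoke_tract += background * keep

    # paint tract values onto the cell grid (constant within each tract)
    k = config.grid_cells_per_tract
    x_edges, y_edges = _grid_edges(config)
    per_tract = smoke_tract.T.reshape(n_days, *nyx)
    smoke_grid = np.kron(per_tract, np.ones((k, k)))

    points = FirePointSet(pd.DataFrame(point_rows, columns=["date", "lon", "lat"]))
    field = DailyField(smoke_grid, dates, x_edges, y_edges, units="ug m-3",
                       crs=tracts.crs, name="smoke_pm25")
    truth = pd.DataFrame(truth_rows, columns=["tract_id", "date", "event"])
    truth = truth.drop_duplicates().reset_index(drop=True)
    return points, field, truth


def tract_smoke_matrix(smoke_tract: np.ndarray, tracts: TractTable,
                       dates: pd.DatetimeIndex) -> TractDayMatrix:
    return TractDayMatrix(smoke_tract, tracts.tract_ids, dates, name="smoke_pm25")


def simulate_bundle(config: SimConfig) -> SyntheticBundle:
    """Run the full generator with one RNG stream in fixed order."""
    rng = np.random.default_rng(config.seed)
    tracts = simulate_tracts(config, rng)
    temperature, heat_truth = simulate_temperature(config, tracts, rng)
    fire_points, smoke, fire_truth = simulate_fires_and_smoke(config, tracts, rng)
    truth = pd.concat([heat_truth, fire_truth], ignore_index=True)
    return SyntheticBundle(config, tracts, temperature, fire_points, smoke, truth)
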