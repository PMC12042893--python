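import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from cohaz.containers import TractTable
from cohaz.geo_io import points_to_counts, zonal_mean
from cohaz.synthetic import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(seed=11, n_tracts_x=4, n_tracts_y=4,
                     years=(2006, 2007), grid_cells_per_tract=2)


@pytest.fixture(scope="session")
def bundle(tiny_config):
    return simulate_bundle(tiny_config)


@pytest.fixture(scope="session")
def recovery_config():
    """Noise-free climate that never crosses the absolute threshold on
    its own, sparse planted heat events with a large excess, and
    plume-only smoke — planted events are exactly recoverable."""
    return SimConfig(
        seed=5, n_tracts_x=4, n_tracts_y=4, years=tuple(range(2006, 2011)),
        base_temp_c=10.0, seasonal_amplitude_c=18.0, noise_sd_c=0.0,
        heat_event_rate=0.15, heat_event_excess_c=30.0,
        fire_ignition_rate=0.5, smoke_background_zero_prob=1.0,
        smoke_plume_radius=2, smoke_decay=0.5,
    )


@pytest.fixture(scope="session")
def recovery_bundle(recovery_config):
    return simulate_bundle(recovery_config)


@pytest.fixture(scope="session")
def recovery_tract_data(recovery_bundle):
    """Tract x day inputs aggregated from the recovery bundle."""
    b = recovery_bundle
    tmax = zonal_mean(b.temperature, b.tracts)
    smoke = zonal_mean(b.smoke, b.tracts)
    counts, unassigned = points_to_counts(b.fire_points, b.tracts,
                                          b.temperature.dates)
    return {"tmax": tmax, "smoke": smoke, "counts": counts,
            "unassigned": unassigned}


def planar_tract_table(n: int = 4, size: float = 1.0,
                       populations=None) -> TractTable:
    """A planar n x n unit-square tract lattice for hand-checkable tests."""
    rows = []
    k = 0
    if populations is None:
        populations = [1000.0] * (n * n)
    for iy in range(n):
        for ix in range(n):
            rows.append({
                "tract_id": f"{k:06d}",
                "state": "A" if ix < n // 2 else "B",
                "county": "C1",
                "population": float(populations[k]),
                "hispanic": 0.2, "nh_white": 0.5, "nh_black": 0.1,
                "nh_asian": 0.1, "nh_aian": 0.05, "nh_other": 0.05,
                "svi": np.nan if populations[k] == 0 else 0.5,
                "pct_65plus": 15.0, "pct_disability": 10.0,
                "pct_poverty150": 20.0,
                "tribal_overlap": False, "coastal": ix == 0,
                "geometry": box(ix * size, iy * size,
                                (ix + 1) * size, (iy + 1) * size),
            })
            k += 1
    df = pd.DataFrame(rows)
    # keep the svi-missing-iff-unpopulated invariant for custom populations
    populated = df["population"] > 0
    df.loc[~populated, "svi"] = np.nan
    if populated.sum() >= 2:
        ranks = df.loc[populated, "population"].rank(method="first") - 1
        df.loc[populated, "svi"] = ranks / (populated.sum() - 1)
    return TractTable(df, crs="planar")
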