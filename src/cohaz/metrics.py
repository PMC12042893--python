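"""Exposure and person-day metrics from tract-day flag matrices.

For a hazard (or coexposure combination) with per-tract exposure days
:math:`E_i` summed over the study period and fixed tract populations
:math:`P_i`, the seven reported metrics are

.. math::

    T_{year} = \\frac{\\sum_i E_i}{N_{years}}, \\qquad
    T_{ct,year} = \\frac{1}{N_{cts}} \\frac{\\sum_i E_i}{N_{years}},

    PDE_i = P_i E_i, \\qquad
    T_{person,year} = \\frac{\\sum_i PDE_i}{N_{years}}, \\qquad
    T_{person,ct,year} = \\frac{1}{N_{cts}} \\frac{\\sum_i PDE_i}{N_{years}},

    T_{S,year} = \\frac{\\sum_{i \\in S} E_i}{N_{years}}, \\qquad
    T_{person,S,year} = \\frac{\\sum_{i \\in S} PDE_i}{N_{years}},

i.e. annual-average tract-days and person-days region-wide, per tract,
and per state.  Person-day metrics assume the whole tract population is
exposed on an exposed tract-day.  A tract-day exposed to several
hazards contributes one day to each hazard's metric and one to their
coexposure metric (no deduplication).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import TractDayMatrix, ValidationError

#: metric name -> units
METRIC_UNITS = {
    "T_year": "tract-days/year",
    "T_ct_year": "days/tract/year",
    "PDE_i": "person-days",
    "T_person_year": "person-days/year",
    "T_person_ct_year": "person-days/tract/year",
    "T_S_year": "tract-days/year",
    "T_person_S_year": "person-days/year",
}


def _require_boolean(flags: TractDayMatrix) -> None:
    if not flags.is_boolean:
        raise ValidationError(f"{flags.name}: expected a boolean flag matrix")


def exposure_days_per_tract(flags: TractDayMatrix) -> tuple[pd.Series, pd.DataFrame]:
    """Per-tract total exposure days E_i and their split by year E_{i,y}."""
    _require_boolean(flags)
    e_i = pd.Series(flags.values.sum(axis=1), index=flags.tract_ids, name="E_i")
    years = flags.years()
    cols = {}
    for y in np.unique(years):
        cols[int(y)] = flags.values[:, years == y].sum(axis=1)
    e_iy = pd.DataFrame(cols, index=flags.tract_ids)
    return e_i, e_iy


def compute_metrics(
    e_i: pd.Series,
    populations: pd.Series,
    state_labels: pd.Series,
    n_years: int,
    combination: str = "hazard",
) -> pd.DataFrame:
    """Tidy table of the seven metrics for one hazard/combination.

    ``e_i`` are per-tract exposure days over the whole study period,
    indexed by tract_id; ``populations`` and ``state_labels`` must align.
    """
    if n_years < 1:
        raise ValidationError("n_years must be >= 1")
    populations = populations.reindex(e_i.index)
    if populations.isna().any():
        missing = populations.index[populations.isna()].tolist()
        raise ValidationError(f"population missing for tracts {missing}")
    state_labels = state_labels.reindex(e_i.index)
    n_cts = len(e_i)

    pde = populations * e_i
    rows = [
        ("region", "all", "T_year", e_i.sum() / n_years),
        ("region", "all", "T_ct_year", e_i.sum() / n_years / n_cts),
        ("region", "all", "T_person_year", pde.sum() / n_years),
        ("region", "all", "T_person_ct_year", pde.sum() / n_years / n_cts),
    ]
    for state, grp in e_i.groupby(state_labels):
        rows.append(("state", state, "T_S_year", grp.sum() / n_years))
    for state, grp in pde.groupby(state_labels):
        rows.append(("state", state, "T_person_S_year", grp.sum() / n_years))
    for tid, val in pde.items():
        rows.append(("tract", tid, "PDE_i", float(val)))

    out = pd.DataFrame(rows, columns=["scope", "scope_id", "metric", "value"])
    out.insert(0, "combination", combination)
    out["units"] = out["metric"].map(METRIC_UNITS)
    return out


def monthly_distribution(flags: TractDayMatrix) -> pd.Series:
    """Percent of flagged tract-days falling in each calendar month.

    Sums to 100 whenever any tract-day is flagged; all-zero (with a
    warning) otherwise.
    """
    _require_boolean(flags)
    months = flags.dates.month.to_numpy()
    per_month = np.array(
        [flags.values[:, months == m].sum() for m in range(1, 13)], dtype=float
    )
    total = per_month.sum()
    if total == 0:
        warnings.warn(f"{flags.name}: no flagged tract-days; "
                      "monthly distribution is all zero")
        pct = per_month
    else:
        pct = per_month / total * 100.0
    return pd.Series(pct, index=pd.Index(range(1, 13), name="month"),
                     name=f"{flags.name}_pct")


def annual_series(flags: TractDayMatrix) -> pd.Series:
    """Total flagged tract-days per calendar year (trend-test input)."""
    _require_boolean(flags)
    years = flags.years()
    uniq = np.unique(years)
    vals = [int(flags.values[:, years == y].sum()) for y in uniq]
    return pd.Series(vals, index=pd.Index(uniq.astype(int), name="year"),
                     name=flags.name)


def annual_person_series(flags: TractDayMatrix, populations: pd.Series) -> pd.Series:
    """Total person-days per calendar year."""
    _require_boolean(flags)
    pops = populations.reindex(flags.tract_ids).to_numpy()
    years = flags.years()
    uniq = np.unique(years)
    vals = [float(pops @ flags.values[:, years == y].sum(axis=1)) for y in uniq]
    return pd.Series(vals, index=pd.Index(uniq.astype(int), name="year"),
                     name=f"{flags.name}_person")


def summarize_combinations(
    matrices: dict[str, TractDayMatrix],
    populations: pd.Series,
    state_labels: pd.Series,
    n_years: int,
) -> pd.DataFrame:
    """Stack :func:`compute_metrics` over hazards/combinations."""
    parts = [
        compute_metrics(exposure_days_per_tract(m)[0], populations,
                        state_labels, n_years, combination=name)
        for name, m in matrices.items()
    ]
    return pd.concat(parts, ignore_index=True)


def round_report(value: float, kind: str = "per_tract") -> float:
    """Reporting convention: one decimal for per-tract averages,
    integers for totals.  Raw values are kept elsewhere."""
    if kind == "per_tract":
        return round(float(value), 1)
    return float(round(float(value)))
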