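"""Sociodemographic distribution of exposure.

Descriptive environmental-justice analyses:

* quintile (or manual-category) composition — the percent of each
  racial/ethnic group's population living in tracts of each exposure
  category; 20% per quintile under an even distribution;
* an SVI overlay flagging tracts that are both highly socially
  vulnerable (SVI > 0.9) and exposed;
* binary-group comparisons (e.g. tribal-land vs other tracts) of mean
  exposure days after a restriction such as "at least one burn-zone
  day";
* top-N most-exposed tract tables with their sociodemographic profile.

Group populations are P_i x share (fractional persons kept).  Zero-
population tracts are excluded from quintile construction, mirroring
how the SVI ranking drops them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import RACE_GROUPS, TractTable, ValidationError

#: invented default day-count edges for burn-zone style skewed exposures:
#: categories [0], [1-2], [3-5], [6-10], [>=11]
DEFAULT_MANUAL_EDGES = (0, 2, 5, 10)


class DegenerateBinsError(ValidationError):
    """All exposure values identical — quintile breaks are undefined;
    use manual categories instead."""


def _composition(
    cat: pd.Series,
    categories: list[str],
    tracts: TractTable,
    groups: list[str],
) -> pd.DataFrame:
    data = tracts.data.set_index("tract_id").loc[cat.index]
    rows = []
    for g in groups:
        gpop = data["population"] * data[g]
        total = gpop.sum()
        for c in categories:
            in_cat = gpop[cat == c].sum()
            pct = 0.0 if total == 0 else in_cat / total * 100.0
            rows.append({"category": c, "group": g, "percent": pct})
    return pd.DataFrame(rows)


def quintile_composition(
    e_i: pd.Series,
    tracts: TractTable,
    groups: list[str] | None = None,
    weighted_breaks: bool = False,
) -> pd.DataFrame:
    """Percent of each group's population per exposure quintile.

    Breaks are the 20/40/60/80th percentiles of the tract E_i
    distribution over populated tracts (unweighted by default;
    ``weighted_breaks`` uses population-weighted percentiles).  A tract
    whose E_i equals a break goes to the lower quintile.
    """
    if groups is None:
        groups = list(RACE_GROUPS)
    pop = tracts.population.reindex(e_i.index)
    e = e_i[pop > 0]
    if e.empty:
        raise ValidationError("no populated tracts")
    if e.nunique() == 1:
        raise DegenerateBinsError(
            "all exposure values identical; quintile breaks are degenerate — "
            "use manual_category_composition"
        )
    if weighted_breaks:
        order = np.argsort(e.to_numpy(), kind="stable")
        w = pop[e.index].to_numpy()[order]
        cum = np.cumsum(w) / w.sum()
        breaks = [e.to_numpy()[order][np.searchsorted(cum, q)] for q in
                  (0.2, 0.4, 0.6, 0.8)]
    else:
        breaks = np.percentile(e.to_numpy(), [20, 40, 60, 80], method="linear")
    labels = ["I", "II", "III", "IV", "V"]
    # side="left": a value equal to a break falls in the lower quintile
    idx = np.searchsorted(breaks, e.to_numpy(), side="left")
    cat = pd.Series([labels[i] for i in idx], index=e.index)
    out = _composition(cat, labels, tracts, groups)
    out["scheme"] = "quintile"
    return out


def manual_category_composition(
    e_i: pd.Series,
    tracts: TractTable,
    edges: tuple[float, ...] = DEFAULT_MANUAL_EDGES,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Composition over manual day-count categories.

    ``edges`` = (0, e1, e2, ...) strictly increasing; categories are
    [0], [1, e1], (e1, e2], ..., (e_last, inf).  Suits burn-zone style
    exposures where most tracts have zero days.
    """
    if groups is None:
        groups = list(RACE_GROUPS)
    edges = tuple(edges)
    if len(edges) < 2 or edges[0] != 0 or any(
        b <= a for a, b in zip(edges, edges[1:])
    ):
        raise ValidationError(
            f"edges must start at 0 and be strictly increasing, got {edges}"
        )
    pop = tracts.population.reindex(e_i.index)
    e = e_i[pop > 0]
    labels = ["0"]
    lo = 1
    for ub in edges[1:]:
        labels.append(f"{lo}-{int(ub)}")
        lo = int(ub) + 1
    labels.append(f">={lo}")

    def assign(v: float) -> str:
        if v == 0:
            return labels[0]
        for k, ub in enumerate(edges[1:], start=1):
            if v <= ub:
                return labels[k]
        return labels[-1]

    cat = e.map(assign)
    out = _composition(cat, labels, tracts, groups)
    out["scheme"] = "manual"
    return out


def svi_overlay(
    e_i: pd.Series,
    tracts: TractTable,
    svi_cut: float = 0.9,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Tracts that are both highly vulnerable and exposed.

    Flag = (SVI strictly above ``svi_cut``) AND (at least one exposure
    day).  Returns the per-tract boolean Series, per-state counts, and
    the number of populated tracts skipped for missing SVI.
    """
    data = tracts.data.set_index("tract_id").loc[e_i.index]
    populated = data["population"] > 0
    missing = populated & data["svi"].isna()
    n_missing = int(missing.sum())
    if n_missing:
        warnings.warn(f"{n_missing} populated tracts lack SVI; excluded")
    flag = (data["svi"] > svi_cut) & (e_i >= 1) & ~missing
    flag.name = "high_svi_exposed"
    by_state = (
        flag.groupby(data["state"]).sum().rename("n_high_svi_exposed").reset_index()
    )
    return flag, by_state, n_missing


def compare_groups(
    days: pd.Series,
    tracts: TractTable,
    flag_name: str = "tribal_overlap",
    restrict: pd.Series | None = None,
) -> pd.DataFrame:
    """Mean exposure days in flagged vs unflagged tracts.

    ``restrict`` (boolean per tract, e.g. ">= 1 burn-zone day") limits
    the comparison cohort first; both sides must stay nonempty.
    """
    data = tracts.data.set_index("tract_id").loc[days.index]
    if flag_name not in data.columns:
        raise ValidationError(f"no tract flag column {flag_name!r}")
    keep = pd.Series(True, index=days.index)
    if restrict is not None:
        keep &= restrict.reindex(days.index).fillna(False).astype(bool)
    flag = data[flag_name].astype(bool)
    sides = []
    for label, mask in ((True, flag & keep), (False, ~flag & keep)):
        if not mask.any():
            raise ValidationError(
                f"restriction leaves no tracts with {flag_name}={label}"
            )
        sides.append({
            flag_name: label,
            "n_tracts": int(mask.sum()),
            "mean_days": float(days[mask].mean()),
        })
    return pd.DataFrame(sides)


def top_tracts(
    e_i: pd.Series,
    tracts: TractTable,
    n: int = 10,
) -> pd.DataFrame:
    """The n tracts with the most cumulative exposure days.

    Descending by days, ties broken by tract_id; includes the all-tract
    average for comparison and the non-white percent (100 - NH-white %).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    data = tracts.data.set_index("tract_id").loc[e_i.index]
    avg = float(e_i.mean())
    frame = pd.DataFrame({
        "days": e_i,
        "state": data["state"],
        "county": data["county"],
        "pct_65plus": data["pct_65plus"],
        "pct_disability": data["pct_disability"],
        "nonwhite_pct": 100.0 * (1.0 - data["nh_white"]),
        "pct_poverty150": data["pct_poverty150"],
    })
    frame = frame.sort_values(
        ["days", "tract_id"], ascending=[False, True],
        kind="stable",
    ).head(n)
    frame["cohort_avg_days"] = avg
    return frame.reset_index()
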