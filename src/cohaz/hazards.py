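"""Tract-day hazard classification.

Three daily hazards are flagged per tract:

* **EH** (extreme heat): daily maximum temperature at or above BOTH a
  tract-specific relative threshold — the 95th percentile of
  warm-season (May-Sep) daily maxima over a 5-year baseline — and an
  absolute threshold of 32.22 degC (90 degF).  The dual threshold keeps
  acclimatisation in the definition while preventing implausibly low
  cut-offs in cool climates.  Classification runs year-round; only the
  threshold derivation is season-restricted.
* **WFBZ** (wildfire burn zone): at least one active-fire point
  detected inside the tract that day.
* **WFS** (wildfire smoke): modelled wildfire-specific PM2.5 strictly
  above a threshold (0 ug/m3 by default; 5 ug/m3 as a sensitivity
  option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TractDayMatrix, ValidationError, require_aligned

ABSOLUTE_EH_THRESHOLD_C = 32.22          # 90 degF
DEFAULT_WARM_SEASON = (5, 9)             # May 1 - Sep 30 inclusive
DEFAULT_BASELINE_N_YEARS = 5


@dataclass
class EHThresholds:
    """Per-tract relative thresholds plus the shared absolute gate."""

    relative_c: pd.Series                # index: tract_id
    absolute_c: float
    baseline_years: list[int]
    warm_season: tuple[int, int]
    percentile: float

    @property
    def share_below_absolute(self) -> float:
        """Fraction of tracts whose relative threshold is below the
        absolute one (those tracts are gated by the absolute threshold)."""
        return float((self.relative_c < self.absolute_c).mean())


@dataclass
class HazardFlags:
    """Aligned boolean tract x day matrices for the three hazards."""

    eh: TractDayMatrix
    wfbz: TractDayMatrix
    wfs: TractDayMatrix
    wfs_threshold_ugm3: float = 0.0

    def __post_init__(self) -> None:
        require_aligned(self.eh, self.wfbz, self.wfs)
        for m in (self.eh, self.wfbz, self.wfs):
            if not m.is_boolean:
                raise ValidationError(f"{m.name} flags must be boolean")

    def as_dict(self) -> dict[str, TractDayMatrix]:
        return {"eh": self.eh, "wfbz": self.wfbz, "wfs": self.wfs}


def warm_season_mask(dates: pd.DatetimeIndex,
                     warm_season: tuple[int, int] = DEFAULT_WARM_SEASON) -> np.ndarray:
    lo, hi = warm_season
    m = dates.month.to_numpy()
    return (m >= lo) & (m <= hi)


def default_baseline_years(dates: pd.DatetimeIndex,
                           n_years: int = DEFAULT_BASELINE_N_YEARS) -> list[int]:
    """First ``n_years`` calendar years of the study window (fewer if the
    window is shorter)."""
    years = sorted(set(dates.year))
    return years[:n_years]


def derive_eh_thresholds(
    tmax: TractDayMatrix,
    baseline_years: list[int] | None = None,
    warm_season: tuple[int, int] = DEFAULT_WARM_SEASON,
    percentile: float = 95.0,
    absolute_c: float = ABSOLUTE_EH_THRESHOLD_C,
) -> EHThresholds:
    """Per-tract relative threshold: the given percentile (linear
    interpolation between order statistics) of warm-season daily maxima
    across the baseline years."""
    if baseline_years is None:
        baseline_years = default_baseline_years(tmax.dates)
    study_years = set(tmax.dates.year)
    if not set(baseline_years) <= study_years:
        raise ValidationError(
            f"baseline years {sorted(set(baseline_years) - study_years)} "
            f"outside the study window"
        )
    mask = warm_season_mask(tmax.dates, warm_season) & np.isin(
        tmax.dates.year.to_numpy(), list(baseline_years)
    )
    if not mask.any():
        raise ValidationError("empty baseline window")
    rel = np.percentile(tmax.values[:, mask], percentile, axis=1,
                        method="linear")
    return EHThresholds(
        relative_c=pd.Series(rel, index=tmax.tract_ids, name="relative_c"),
        absolute_c=absolute_c,
        baseline_years=list(baseline_years),
        warm_season=warm_season,
        percentile=percentile,
    )


def classify_eh(tmax: TractDayMatrix, thresholds: EHThresholds) -> TractDayMatrix:
    """EH flag: tmax >= relative AND tmax >= absolute (both inclusive),
    on every day of every study year."""
    if not tmax.tract_ids.equals(thresholds.relative_c.index):
        raise ValidationError("threshold tracts do not match tmax tracts")
    rel = thresholds.relative_c.to_numpy()[:, None]
    flags = (tmax.values >= rel) & (tmax.values >= thresholds.absolute_c)
    return TractDayMatrix(flags, tmax.tract_ids, tmax.dates, name="eh")


def classify_wfbz(fire_counts: TractDayMatrix) -> TractDayMatrix:
    """WFBZ flag: at least one fire point in the tract that day."""
    counts = fire_counts.values
    if (counts < 0).any():
        raise ValidationError("negative fire counts")
    return TractDayMatrix(counts >= 1, fire_counts.tract_ids,
                          fire_counts.dates, name="wfbz")


def classify_wfs(smoke: TractDayMatrix, threshold_ugm3: float = 0.0) -> TractDayMatrix:
    """WFS flag: smoke PM2.5 strictly above the threshold."""
    if (smoke.values < 0).any():
        raise ValidationError("negative smoke concentrations")
    return TractDayMatrix(smoke.values > threshold_ugm3, smoke.tract_ids,
                          smoke.dates, name="wfs")


def classify_all(
    tmax: TractDayMatrix,
    fire_counts: TractDayMatrix,
    smoke: TractDayMatrix,
    baseline_years: list[int] | None = None,
    warm_season: tuple[int, int] = DEFAULT_WARM_SEASON,
    percentile: float = 95.0,
    wfs_threshold_ugm3: float = 0.0,
    absolute_c: float = ABSOLUTE_EH_THRESHOLD_C,
) -> tuple[HazardFlags, EHThresholds]:
    """Derive EH thresholds and produce all three aligned flag matrices."""
    require_aligned(tmax, fire_counts, smoke)
    thresholds = derive_eh_thresholds(
        tmax, baseline_years, warm_season, percentile, absolute_c
    )
    flags = HazardFlags(
        eh=classify_eh(tmax, thresholds),
        wfbz=classify_wfbz(fire_counts),
        wfs=classify_wfs(smoke, wfs_threshold_ugm3),
        wfs_threshold_ugm3=wfs_threshold_ugm3,
    )
    return flags, thresholds
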