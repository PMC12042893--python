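"""Coexposure flags: two or more hazards in the same tract.

Same-day coexposure is the elementwise AND of hazard flags — two or
more hazards occurring simultaneously in the same tract on the same
day.  The 2-day sensitivity window additionally pairs events on
adjacent days: a tract-day is flagged for pair (A, B) when A occurs
that day and B occurs within one day of it, or vice versa.  By default
BOTH participating days receive the flag (so one EH day adjacent to one
WFBZ day yields two coexposure tract-days); ``credit="later"`` flags
only the later day of each adjacent pair.

The triple combination under the 2-day window requires all three
pairwise conditions to hold on the day (which implies at least one
hazard is active then).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TractDayMatrix, ValidationError
from .hazards import HazardFlags

#: Combination keys, in canonical order.
COMBINATIONS = ["eh_wfbz", "eh_wfs", "wfbz_wfs", "eh_wfbz_wfs"]

PAIRS = {"eh_wfbz": ("eh", "wfbz"), "eh_wfs": ("eh", "wfs"),
         "wfbz_wfs": ("wfbz", "wfs")}


@dataclass
class CoexposureFlags:
    """One boolean tract x day matrix per hazard combination."""

    eh_wfbz: TractDayMatrix
    eh_wfs: TractDayMatrix
    wfbz_wfs: TractDayMatrix
    eh_wfbz_wfs: TractDayMatrix
    window: str = "same_day"

    def as_dict(self) -> dict[str, TractDayMatrix]:
        return {c: getattr(self, c) for c in COMBINATIONS}


def _dilate(a: np.ndarray) -> np.ndarray:
    """True where a is true on day d-1, d or d+1 (series boundaries use
    only existing neighbours)."""
    out = a.copy()
    out[:, 1:] |= a[:, :-1]
    out[:, :-1] |= a[:, 1:]
    return out


def _shift_earlier(a: np.ndarray) -> np.ndarray:
    """a shifted so column d holds a[d-1] (False at the start)."""
    out = np.zeros_like(a)
    out[:, 1:] = a[:, :-1]
    return out


def coexpose_same_day(flags: HazardFlags) -> CoexposureFlags:
    """Same-day coexposure: elementwise AND per combination."""
    eh, wfbz, wfs = flags.eh.values, flags.wfbz.values, flags.wfs.values
    ids, dates = flags.eh.tract_ids, flags.eh.dates

    def m(v: np.ndarray, name: str) -> TractDayMatrix:
        return TractDayMatrix(v, ids, dates, name=name)

    return CoexposureFlags(
        eh_wfbz=m(eh & wfbz, "eh_wfbz"),
        eh_wfs=m(eh & wfs, "eh_wfs"),
        wfbz_wfs=m(wfbz & wfs, "wfbz_wfs"),
        eh_wfbz_wfs=m(eh & wfbz & wfs, "eh_wfbz_wfs"),
        window="same_day",
    )


def _pair_two_day(a: np.ndarray, b: np.ndarray, credit: str) -> np.ndarray:
    if credit == "both":
        return (a & _dilate(b)) | (b & _dilate(a))
    if credit == "later":
        # the later day of each within-window (A, B) occurrence:
        # B today with A today-or-yesterday, or A today with B yesterday
        return (b & (a | _shift_earlier(a))) | (a & _shift_earlier(b))
    raise ValidationError(f"unknown credit rule {credit!r}")


def coexpose_two_day(flags: HazardFlags, credit: str = "both") -> CoexposureFlags:
    """2-day-window coexposure.

    Pair (A, B) flags tract-day d when A on d pairs with B on d-1, d or
    d+1, or symmetrically.  ``credit`` chooses whether both days of an
    adjacent pair are flagged (default) or only the later one.  The
    triple is the conjunction of the three pairwise flags.
    """
    eh, wfbz, wfs = flags.eh.values, flags.wfbz.values, flags.wfs.values
    ids, dates = flags.eh.tract_ids, flags.eh.dates

    p_eh_wfbz = _pair_two_day(eh, wfbz, credit)
    p_eh_wfs = _pair_two_day(eh, wfs, credit)
    p_wfbz_wfs = _pair_two_day(wfbz, wfs, credit)
    triple = p_eh_wfbz & p_eh_wfs & p_wfbz_wfs

    def m(v: np.ndarray, name: str) -> TractDayMatrix:
        return TractDayMatrix(v, ids, dates, name=name)

    return CoexposureFlags(
        eh_wfbz=m(p_eh_wfbz, "eh_wfbz"),
        eh_wfs=m(p_eh_wfs, "eh_wfs"),
        wfbz_wfs=m(p_wfbz_wfs, "wfbz_wfs"),
        eh_wfbz_wfs=m(triple, "eh_wfbz_wfs"),
        window="two_day",
    )


def coexpose(flags: HazardFlags, window: str = "same_day",
             credit: str = "both") -> CoexposureFlags:
    if window == "same_day":
        return coexpose_same_day(flags)
    if window == "two_day":
        return coexpose_two_day(flags, credit=credit)
    raise ValidationError(f"unknown coexposure window {window!r}")
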