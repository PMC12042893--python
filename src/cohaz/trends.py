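"""Mann-Kendall trend test for annual exposure series.

The classical nonparametric test: for a series :math:`x_1..x_n`,

.. math:: S = \\sum_{i<j} \\mathrm{sgn}(x_j - x_i)

with tie-corrected variance

.. math:: \\mathrm{var}(S) = \\frac{n(n-1)(2n+5) - \\sum_t t(t-1)(2t+5)}{18}

(sum over groups of tied values of extent :math:`t`), a
continuity-corrected normal deviate

.. math:: Z = \\begin{cases}(S-1)/\\sqrt{\\mathrm{var}(S)} & S>0\\\\
   0 & S=0\\\\ (S+1)/\\sqrt{\\mathrm{var}(S)} & S<0\\end{cases}

and a two-sided normal p-value.  No seasonal or
autocorrelation-corrected variants are applied.  With annual series of
~15 years the test is low-powered; results on short series carry a
small-sample caution flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import ValidationError

SMALL_N_CAUTION = 10


@dataclass
class TrendResult:
    n: int
    s: int
    var_s: float
    z: float
    p_two_sided: float
    direction: str          # increasing | decreasing | none
    alpha: float = 0.05

    def as_row(self) -> dict:
        return {
            "n": self.n, "S": self.s, "var_S": self.var_s, "Z": self.z,
            "p": self.p_two_sided, "direction": self.direction,
            "alpha": self.alpha,
        }


def mann_kendall(series, alpha: float = 0.05) -> TrendResult:
    """Two-sided Mann-Kendall test on an ordered series (n >= 3)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError("Mann-Kendall needs a 1-D series with n >= 3")
    if np.isnan(x).any():
        raise ValidationError("Mann-Kendall series contains NaN")
    n = len(x)
    s = int(np.sign(x[None, :] - x[:, None])[np.triu_indices(n, k=1)].sum())

    _, tie_counts = np.unique(x, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0

    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 1.0 if s == 0 else float(2.0 * norm.sf(abs(z)))
    p = min(p, 1.0)

    if p <= alpha and s > 0:
        direction = "increasing"
    elif p <= alpha and s < 0:
        direction = "decreasing"
    else:
        direction = "none"
    return TrendResult(n=n, s=s, var_s=float(var_s), z=float(z),
                       p_two_sided=p, direction=direction, alpha=alpha)


def exact_permutation_p(series) -> float:
    """Exact two-sided p-value of |S| by full permutation enumeration.

    Independent check of the normal approximation; O(n!) so only viable
    for n <= ~8.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n > 8:
        raise ValidationError("exact permutation test limited to n <= 8")

    def s_stat(v: np.ndarray) -> int:
        return int(np.sign(v[None, :] - v[:, None])[np.triu_indices(n, k=1)].sum())

    s_obs = abs(s_stat(x))
    count = total = 0
    for perm in permutations(x):
        total += 1
        if abs(s_stat(np.asarray(perm))) >= s_obs:
            count += 1
    return count / total


def trend_table(
    annual: pd.DataFrame,
    alpha: float = 0.05,
    skip_short: bool = False,
) -> pd.DataFrame:
    """Mann-Kendall per (scope, combination) annual series.

    ``annual`` is tidy with columns (scope, combination, year, value).
    Adds a ``small_n_caution`` flag for series shorter than
    :data:`SMALL_N_CAUTION` years; p-values are also reported rounded to
    3 decimals alongside the raw value.  Series shorter than 3 years
    raise unless ``skip_short``, in which case their row carries NaN
    statistics and direction ``"insufficient_years"``.
    """
    required = {"scope", "combination", "year", "value"}
    if not required <= set(annual.columns):
        raise ValidationError(f"annual table needs columns {sorted(required)}")
    rows = []
    for (scope, comb), grp in annual.groupby(["scope", "combination"]):
        grp = grp.sort_values("year")
        values = grp["value"].to_numpy()
        if len(values) < 3 and skip_short:
            row = {"scope": scope, "combination": comb, "n": len(values),
                   "S": np.nan, "var_S": np.nan, "Z": np.nan, "p": np.nan,
                   "direction": "insufficient_years", "alpha": alpha,
                   "p_rounded": np.nan, "small_n_caution": True}
            rows.append(row)
            continue
        res = mann_kendall(values, alpha=alpha)
        row = {"scope": scope, "combination": comb, **res.as_row()}
        row["p_rounded"] = round(res.p_two_sided, 3)
        row["small_n_caution"] = res.n < SMALL_N_CAUTION
        rows.append(row)
    return pd.DataFrame(rows)
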