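"""Nonparametric trend detection: Mann-Kendall test and Sen's slope.

The Mann-Kendall statistic S counts concordant minus discordant pairs of a
time series; under the no-trend null it is asymptotically normal with mean
zero and a variance corrected for tied values. Sen's slope, the median of
all pairwise slopes, provides a robust trend magnitude in series units per
time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["TrendResult", "mann_kendall", "sens_slope", "trend_suite"]


@dataclass(frozen=True)
class TrendResult:
    """Outcome of the Mann-Kendall test and Sen's slope for one series."""

    S: int
    var_S: float
    Z: float
    p_value: float
    slope: float
    direction: str  # "up", "down" or "none"
    significant: bool
    n: int
    alpha: float = 0.05
    small_sample: bool = False  # normal approximation asserted for n > 10 only


def mann_kendall(series, alpha: float = 0.05) -> TrendResult:
    """Two-sided Mann-Kendall trend test with tie-corrected variance.

    S = sum over pairs j > k of sgn(x_j - x_k);
    Var(S) = [n(n-1)(2n+5) - sum_i e_i(e_i-1)(2e_i+5)] / 18
    with e_i the extent of each group of tied values; the standardized
    statistic uses a continuity correction:
    Z = (S - 1)/sqrt(Var) for S > 0, 0 for S = 0, (S + 1)/sqrt(Var) for S < 0.

    Requires n >= 4. For 4 <= n <= 10 the result carries a
    ``small_sample`` flag (and a warning) because the normal approximation
    is only asserted for n > 10. An all-equal series yields S = 0, Z = 0,
    direction "none".
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("Mann-Kendall test requires a 1-d series with n >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("series values must be finite")
    n = len(x)

    diffs = np.sign(x[:, None] - x[None, :])  # diffs[j, k] = sgn(x_j - x_k)
    s = int(np.sum(np.tril(diffs, -1)))

    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0

    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * norm.sf(abs(z))
    direction = "up" if z > 0 else ("down" if z < 0 else "none")

    small = n <= 10
    if small:
        warnings.warn(
            f"Mann-Kendall normal approximation is asserted for n > 10 (n={n})",
            stacklevel=2,
        )
    return TrendResult(
        S=s,
        var_S=float(var_s),
        Z=float(z),
        p_value=float(p),
        slope=sens_slope(x),
        direction=direction,
        significant=bool(abs(z) >= norm.isf(alpha / 2.0)),
        n=n,
        alpha=alpha,
        small_sample=small,
    )


def sens_slope(series) -> float:
    """Sen's slope: the median of (x_j - x_k)/(j - k) over all pairs j > k."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("Sen's slope requires a 1-d series with n >= 2")
    n = len(x)
    idx = np.arange(n)
    j, k = np.triu_indices(n, 1)  # j < k here; slope symmetric in the pair
    slopes = (x[k] - x[j]) / (idx[k] - idx[j])
    return float(np.median(slopes))


def trend_suite(
    panel: pd.DataFrame,
    value_col: str = "value",
    site_col: str = "site",
    time_col: str = "time",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Apply the Mann-Kendall test and Sen's slope to each site's series.

    ``panel`` is a long DataFrame with one row per (site, time); series are
    sorted by ``time_col`` within site. Returns one row of TrendResult
    fields per site.
    """
    for col in (value_col, site_col, time_col):
        if col not in panel.columns:
            raise ValueError(f"column {col!r} not found in panel")
    if panel.empty:
        raise ValueError("empty panel")
    rows = []
    for site, g in panel.groupby(site_col, sort=False):
        series = g.sort_values(time_col)[value_col].to_numpy(dtype=float)
        res = mann_kendall(series, alpha=alpha)
        rows.append({site_col: site, **res.__dict__})
    return pd.DataFrame(rows)
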