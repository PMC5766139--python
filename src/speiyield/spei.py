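"""Multi-scalar Standardized Precipitation Evapotranspiration Index (SPEI).

The index is computed in three steps for each site and time scale ``k``:

1. the monthly climatic water balance ``D_i = P_i - PET_i``, with potential
   evapotranspiration from the Thornthwaite temperature/daylength method;
2. aggregation of ``D`` over trailing ``k``-month windows, then a
   three-parameter log-logistic distribution fitted separately to each
   calendar month's aggregated values by probability-weighted moments
   (L-moments);
3. mapping of the fitted non-exceedance probability to standard-normal
   units through the classical rational approximation of the normal
   quantile function.

Positive SPEI values indicate wetter-than-usual conditions, negative values
drier-than-usual, on a scale comparable across sites, seasons and scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb, gamma as gamma_fn

from ._exceptions import EstimationError, ValidationError

__all__ = [
    "MoistureLevel",
    "LogLogisticParams",
    "WaterBalanceSeries",
    "SPEISeries",
    "thornthwaite_pet",
    "water_balance",
    "aggregate",
    "fit_loglogistic",
    "loglogistic_cdf",
    "standardize",
    "compute_spei",
    "classify",
]

# Rational-approximation constants for the standard-normal quantile
# (Abramowitz & Stegun 26.2.23); documented maximum absolute error 4.5e-4.
_C0 = 2.515517
_C1 = 0.802853
_C2 = 0.010328
_D1 = 1.432788
_D2 = 0.189269
_D3 = 0.001308

# Probability clamp applied when an aggregated value falls at or below the
# fitted origin (or in the extreme upper tail); affects only extreme tails.
_P_FLOOR = 1e-6

_DAYS_PER_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
# Mid-month day of year (non-leap calendar).
_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349], dtype=float)


class MoistureLevel(Enum):
    """Drought/wetness categories partitioning the SPEI axis.

    Boundaries are half-open, closed on the drought side: e.g. SPEI = -0.5
    is classified as slight drought, SPEI = 0.5 as slight wetting.
    """

    EXTREME_DROUGHT = "extreme drought"
    MODERATE_DROUGHT = "moderate drought"
    SLIGHT_DROUGHT = "slight drought"
    NORMAL = "normal"
    SLIGHT_WETTING = "slight wetting"
    MODERATE_WETTING = "moderate wetting"
    EXTREME_WETTING = "extreme wetting"


@dataclass(frozen=True)
class LogLogisticParams:
    """Fitted three-parameter log-logistic distribution for one calendar month.

    ``alpha`` is the scale (mm), ``beta`` the shape (dimensionless), and
    ``gamma`` the origin (mm): F(x) = [1 + (alpha/(x-gamma))^beta]^-1.
    The usual right-skewed log-logistic has alpha > 0 and beta > 1 with
    support above the origin. For samples whose L-skewness comes out
    negative (possible in finite samples even under a right-skewed truth)
    the same algebraic form with alpha < 0 and beta < 0 is the mirrored,
    left-skewed member of the generalized-logistic family, with support
    below ``gamma``; the fit degrades gracefully instead of failing.
    """

    alpha: float
    beta: float
    gamma: float
    calendar_month: int = 0
    scale_k: int = 1

    def __post_init__(self) -> None:
        if not self.alpha * self.beta > 0:
            raise ValueError("log-logistic scale and shape must share a sign")


@dataclass(frozen=True)
class WaterBalanceSeries:
    """Ordered monthly climatic water balance D = P - PET for one site."""

    site: str
    values: np.ndarray
    month_index: pd.MultiIndex  # (year, month) per value

    def __post_init__(self) -> None:
        if len(self.values) != len(self.month_index):
            raise ValueError("values and month_index must be the same length")


@dataclass
class SPEISeries:
    """SPEI values for one site at one time scale, plus the fitted parameters.

    The first ``scale_k - 1`` months of the record are undefined (NaN): a
    k-month aggregation window cannot be completed there.
    """

    site: str
    scale_k: int
    years: np.ndarray
    months: np.ndarray
    values: np.ndarray
    params: dict[int, LogLogisticParams] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": self.site,
                "year": self.years,
                "month": self.months,
                "scale_k": self.scale_k,
                "spei": self.values,
            }
        )


def _daylength_hours(latitude: float, month: int) -> float:
    """Mean daylength (hours) for a calendar month from solar declination
    at the month's mid-day."""
    phi = math.radians(latitude)
    delta = 0.4093 * math.sin(2.0 * math.pi * _MID_MONTH_DOY[month - 1] / 365.0 - 1.405)
    x = -math.tan(phi) * math.tan(delta)
    x = min(1.0, max(-1.0, x))  # polar day/night
    omega = math.acos(x)
    return 24.0 / math.pi * omega


def thornthwaite_pet(
    monthly_temps: Sequence[float],
    latitude: float,
    start_month: int = 1,
) -> np.ndarray:
    """Monthly potential evapotranspiration (mm) by the Thornthwaite method.

    Parameters
    ----------
    monthly_temps
        Consecutive monthly mean temperatures in °C, at least 12 months.
    latitude
        Site latitude in decimal degrees, positive north.
    start_month
        Calendar month (1-12) of the first value.

    Notes
    -----
    The annual heat index ``I`` is computed from the per-calendar-month mean
    temperatures of the supplied record, ``I = sum((T_m/5)^1.514)`` over
    months with positive means. Unadjusted PET is ``16 (10 T / I)^a`` for
    0 < T < 26.5 °C, zero for T <= 0, and the standard high-temperature
    polynomial ``-415.85 + 32.24 T - 0.43 T^2`` for T >= 26.5 °C, then
    corrected by daylength and days-in-month: ``K = (N/12)(NDM/30)``.
    """
    t = np.asarray(monthly_temps, dtype=float)
    if t.ndim != 1 or len(t) < 12:
        raise ValueError("at least 12 consecutive monthly temperatures are required")
    if not np.all(np.isfinite(t)):
        raise ValueError("temperatures must be finite")
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    if not 1 <= start_month <= 12:
        raise ValueError("start_month must be in 1..12")

    months = (np.arange(len(t)) + start_month - 1) % 12 + 1

    # Heat index from the record's monthly normals.
    monthly_means = np.array([t[months == m].mean() for m in range(1, 13)])
    positive = np.clip(monthly_means, 0.0, None)
    heat_index = float(np.sum((positive[positive > 0] / 5.0) ** 1.514))
    if heat_index <= 0.0:
        return np.zeros_like(t)
    a = (
        6.75e-7 * heat_index**3
        - 7.71e-5 * heat_index**2
        + 1.792e-2 * heat_index
        + 0.49239
    )

    pet = np.zeros_like(t)
    warm = (t > 0.0) & (t < 26.5)
    pet[warm] = 16.0 * (10.0 * t[warm] / heat_index) ** a
    hot = t >= 26.5
    pet[hot] = -415.85 + 32.24 * t[hot] - 0.43 * t[hot] ** 2

    corr = np.array(
        [
            _daylength_hours(latitude, m) / 12.0 * _DAYS_PER_MONTH[m - 1] / 30.0
            for m in months
        ]
    )
    return np.clip(pet * corr, 0.0, None)


def water_balance(
    precip: Sequence[float],
    pet: Sequence[float],
    site: str = "",
    month_index: pd.MultiIndex | None = None,
) -> WaterBalanceSeries:
    """Elementwise climatic water balance ``D_i = P_i - PET_i`` (mm)."""
    p = np.asarray(precip, dtype=float)
    e = np.asarray(pet, dtype=float)
    if p.shape != e.shape:
        raise ValueError("precipitation and PET sequences must have equal length")
    if month_index is None:
        month_index = pd.MultiIndex.from_arrays(
            [np.zeros(len(p), dtype=int), np.arange(len(p)) % 12 + 1],
            names=["year", "month"],
        )
    return WaterBalanceSeries(site=site, values=p - e, month_index=month_index)


def aggregate(d: Sequence[float] | WaterBalanceSeries, k: int) -> np.ndarray:
    """Trailing k-month sums of the water balance.

    The value at position ``m`` is ``sum(D[m-k+1 .. m])``; the first ``k-1``
    positions are NaN (undefined: no complete window).
    """
    values = d.values if isinstance(d, WaterBalanceSeries) else np.asarray(d, dtype=float)
    if k < 1:
        raise ValueError("aggregation scale k must be >= 1")
    if k > len(values):
        raise ValueError("aggregation scale k exceeds series length")
    out = np.convolve(values, np.ones(k), mode="full")[: len(values)]
    out[: k - 1] = np.nan
    return out


def _pwm(x: np.ndarray, order: int, method: str) -> float:
    """Probability-weighted moment a_s = E[X (1-F)^s], ascending order stats.

    ``method="unbiased"`` uses the exact combinatorial estimator;
    ``method="plotting"`` uses the plotting position F_i = (i - 0.35)/n.
    """
    n = len(x)
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    if method == "unbiased":
        w = comb(n - i, order) / comb(n - 1, order)
    elif method == "plotting":
        w = (1.0 - (i - 0.35) / n) ** order
    else:
        raise ValueError(f"unknown PWM method: {method!r}")
    return float(np.mean(w * xs))


def fit_loglogistic(
    samples: Sequence[float],
    calendar_month: int = 0,
    scale_k: int = 1,
    pwm_method: str = "unbiased",
) -> LogLogisticParams:
    """Fit the three-parameter log-logistic distribution by L-moments.

    With probability-weighted moments ``a_s = E[X (1-F)^s]`` the sample
    L-moments are ``l1 = a0``, ``l2 = a0 - 2 a1``, ``l3 = a0 - 6 a1 + 6 a2``
    and the parameters follow from

        beta  = l2 / l3                    (= 1 / tau3)
        alpha = l2 * beta / (G(1 + 1/beta) G(1 - 1/beta))
        gamma = l1 - alpha * G(1 + 1/beta) G(1 - 1/beta)

    For l3 > 0 this is the usual right-skewed log-logistic (beta > 1,
    alpha > 0); for l3 < 0 the same expressions give the mirrored member of
    the generalized-logistic family (beta < 0, alpha < 0), keeping the fit
    defined for finitely left-skewed samples. Requires at least 10 finite
    samples.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise ValueError("at least 10 finite samples are required to fit")
    if np.ptp(x) == 0.0:
        raise EstimationError("degenerate sample: all values identical")

    a0 = _pwm(x, 0, pwm_method)
    a1 = _pwm(x, 1, pwm_method)
    a2 = _pwm(x, 2, pwm_method)

    l1 = a0
    l2 = a0 - 2.0 * a1
    l3 = a0 - 6.0 * a1 + 6.0 * a2
    if l2 <= 0.0:
        raise EstimationError("log-logistic fit failed: non-positive second L-moment")
    tau3 = l3 / l2
    # tau3 = 0 is the logistic limit (beta -> inf); nudge to stay finite.
    if abs(tau3) < 1e-9:
        tau3 = math.copysign(1e-9, tau3 if tau3 != 0.0 else 1.0)
    beta = 1.0 / tau3
    g = gamma_fn(1.0 + 1.0 / beta) * gamma_fn(1.0 - 1.0 / beta)  # = pi/(beta sin(pi/beta))
    alpha = l2 * beta / g
    origin = l1 - alpha * g
    return LogLogisticParams(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(origin),
        calendar_month=calendar_month,
        scale_k=scale_k,
    )


def loglogistic_cdf(x: Sequence[float] | float, params: LogLogisticParams) -> np.ndarray:
    """F(x) = [1 + (alpha/(x-gamma))^beta]^-1, clamped to (1e-6, 1-1e-6).

    For the right-skewed branch (beta > 0) values at or below the origin
    take the floor probability; for the mirrored branch (beta < 0), whose
    support lies below the origin, values at or above it take the ceiling.
    """
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    fill = _P_FLOOR if params.beta > 0 else 1.0 - _P_FLOOR
    out = np.full(xv.shape, fill)
    inside = xv > params.gamma if params.beta > 0 else xv < params.gamma
    z = (params.alpha / (xv[inside] - params.gamma)) ** params.beta
    out[inside] = 1.0 / (1.0 + z)
    return np.clip(out, _P_FLOOR, 1.0 - _P_FLOOR)


def standardize(p_exceed: Sequence[float] | float):
    """Map an exceedance probability P = 1 - F(x) to an SPEI value.

    For P <= 0.5: W = sqrt(-2 ln P) and

        SPEI = W - (C0 + C1 W + C2 W^2) / (1 + d1 W + d2 W^2 + d3 W^3)

    For P > 0.5 the same formula is applied to 1 - P and the sign flipped,
    so wet conditions (small exceedance of the wet tail) map to positive
    values and dry conditions to negative values. Strictly decreasing in P.
    """
    p = np.atleast_1d(np.asarray(p_exceed, dtype=float))
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("exceedance probabilities must lie strictly in (0, 1)")
    flip = p > 0.5
    pp = np.where(flip, 1.0 - p, p)
    w = np.sqrt(-2.0 * np.log(pp))
    z = w - (_C0 + _C1 * w + _C2 * w**2) / (1.0 + _D1 * w + _D2 * w**2 + _D3 * w**3)
    out = np.where(flip, -z, z)
    if np.isscalar(p_exceed) or np.ndim(p_exceed) == 0:
        return float(out[0])
    return out


def classify(spei: float) -> MoistureLevel:
    """Classify one SPEI value into a moisture level.

    Intervals (half-open, closed on the drought side):
    <= -2 extreme drought; (-2, -1] moderate drought; (-1, -0.5] slight
    drought; (-0.5, 0.5) normal; [0.5, 1) slight wetting; [1, 2) moderate
    wetting; >= 2 extreme wetting.
    """
    if not np.isfinite(spei):
        raise ValueError("SPEI value must be finite")
    if spei <= -2.0:
        return MoistureLevel.EXTREME_DROUGHT
    if spei <= -1.0:
        return MoistureLevel.MODERATE_DROUGHT
    if spei <= -0.5:
        return MoistureLevel.SLIGHT_DROUGHT
    if spei < 0.5:
        return MoistureLevel.NORMAL
    if spei < 1.0:
        return MoistureLevel.SLIGHT_WETTING
    if spei < 2.0:
        return MoistureLevel.MODERATE_WETTING
    return MoistureLevel.EXTREME_WETTING


def _check_consecutive(site: str, years: np.ndarray, months: np.ndarray) -> None:
    code = years * 12 + (months - 1)
    gaps = np.flatnonzero(np.diff(code) != 1)
    if len(gaps):
        i = gaps[0] + 1
        raise ValidationError(
            f"climate record for site {site!r} has a gap before "
            f"{int(years[i])}-{int(months[i]):02d}"
        )


def fit_spei_site(
    site_df: pd.DataFrame,
    scale_k: int,
    calibration: tuple[int, int] | None = None,
    pwm_method: str = "unbiased",
) -> SPEISeries:
    """Compute one site's SPEI at one scale from its monthly climate rows.

    ``site_df`` needs columns site, latitude, year, month, tmean_c,
    precip_mm, strictly consecutive in time. ``calibration`` optionally
    restricts the distribution fitting to a (start_year, end_year) window;
    standardization is applied to the whole record either way.
    """
    g = site_df.sort_values(["year", "month"]).reset_index(drop=True)
    site = str(g["site"].iloc[0])
    years = g["year"].to_numpy(dtype=int)
    months = g["month"].to_numpy(dtype=int)
    _check_consecutive(site, years, months)

    lat = float(g["latitude"].iloc[0])
    pet = thornthwaite_pet(g["tmean_c"].to_numpy(float), lat, start_month=int(months[0]))
    d = g["precip_mm"].to_numpy(float) - pet
    agg = aggregate(d, scale_k)

    spei = np.full(len(agg), np.nan)
    params: dict[int, LogLogisticParams] = {}
    for m in range(1, 13):
        mask = (months == m) & np.isfinite(agg)
        if not mask.any():
            continue
        calib = mask.copy()
        if calibration is not None:
            lo, hi = calibration
            calib &= (years >= lo) & (years <= hi)
        p = fit_loglogistic(agg[calib], calendar_month=m, scale_k=scale_k, pwm_method=pwm_method)
        params[m] = p
        cdf = loglogistic_cdf(agg[mask], p)
        spei[mask] = standardize(1.0 - cdf)
    return SPEISeries(site=site, scale_k=scale_k, years=years, months=months, values=spei, params=params)


def compute_spei(
    panel: pd.DataFrame,
    scales: Iterable[int] = (1, 3, 6, 9),
    calibration: tuple[int, int] | None = None,
    pwm_method: str = "unbiased",
) -> pd.DataFrame:
    """Compute SPEI for every site in a monthly climate panel at each scale.

    Returns a long DataFrame (site, year, month, scale_k, spei, level);
    ``spei`` is NaN and ``level`` empty for the undefined k-1 prefix.
    """
    required = {"site", "latitude", "year", "month", "tmean_c", "precip_mm"}
    missing = required - set(panel.columns)
    if missing:
        raise ValidationError(f"climate panel is missing columns: {sorted(missing)}")
    frames = []
    for _, site_df in panel.groupby("site", sort=False):
        for k in scales:
            series = fit_spei_site(site_df, int(k), calibration=calibration, pwm_method=pwm_method)
            frames.append(series.to_frame())
    out = pd.concat(frames, ignore_index=True)
    out["level"] = [
        classify(v).value if np.isfinite(v) else "" for v in out["spei"].to_numpy()
    ]
    return out
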