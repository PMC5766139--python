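"""Synthetic monthly climate panels and annual yield panels.

The generator emulates a small network of mid-latitude monsoon-climate
stations: a sinusoidal seasonal temperature cycle peaking in July, a linear
warming trend, Gaussian month-to-month temperature noise, and monthly
precipitation drawn from gamma distributions whose means follow a fixed
climatological weight vector (wetter May-August) scaled to each site's
annual total, with a north(dry)-south(wet) gradient across sites.

Yields are generated from the quadratic fixed-effects panel model

    Y_it = beta_i + a1 * s_it + a2 * s_it^2 + a3 * t + u_it,
    u_it = rho * u_{i,t-1} + eps_it,   eps_it ~ N(0, error_sd^2),

with the AR(1) error initialized from its stationary distribution per site
and independent across sites. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteSpec",
    "TruePanelParams",
    "default_sites",
    "default_panel_params",
    "generate_climate",
    "generate_yields",
    "MONTHLY_PRECIP_WEIGHTS",
]

# Climatological share of the annual precipitation falling in each calendar
# month (Jan..Dec); wetter May-August reflects the summer monsoon.
MONTHLY_PRECIP_WEIGHTS = np.array(
    [0.04, 0.05, 0.07, 0.08, 0.10, 0.14, 0.18, 0.13, 0.08, 0.06, 0.04, 0.03]
)


@dataclass(frozen=True)
class SiteSpec:
    """Static description of one synthetic station."""

    name: str
    latitude: float  # degrees N
    mean_annual_temp: float  # °C
    annual_precip: float  # mm
    warming_slope: float = 0.05  # °C per year
    temp_seasonal_amplitude: float = 12.5  # °C, July peak
    temp_noise_sd: float = 0.8  # °C
    precip_shape: float = 4.0  # gamma shape per month

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude must lie in [-90, 90]")
        if self.annual_precip <= 0:
            raise ValueError("annual precipitation must be positive")
        if self.precip_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.temp_seasonal_amplitude < 0:
            raise ValueError("seasonal amplitude must be non-negative")
        if self.temp_noise_sd < 0:
            raise ValueError("temperature noise sd must be non-negative")


@dataclass(frozen=True)
class TruePanelParams:
    """True coefficients of the yield-generating panel model."""

    site_intercepts: Mapping[str, float]  # beta_i, t/ha
    alpha1: float  # t/ha per SPEI unit
    alpha2: float  # t/ha per SPEI^2 unit
    alpha3: float  # t/ha per year (technology trend)
    rho: float = 0.0  # AR(1) coefficient
    error_sd: float = 0.0  # t/ha

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1.0:
            raise ValueError("|rho| must be < 1 for a stationary AR(1)")
        if self.error_sd < 0:
            raise ValueError("error sd must be non-negative")


# Station layout inspired by a 10-station network spanning ~31-35°N with
# mean annual temperature 13-16 °C (cooler north) and annual precipitation
# 724-1210 mm (drier north); warming slopes span 0.04-0.07 °C/yr.
_STATIONS = [
    ("Ganyu", 34.50),
    ("Xuzhou", 34.17),
    ("Xuyi", 32.58),
    ("Dongtai", 32.52),
    ("Gaoyou", 32.48),
    ("Yangzhou", 32.25),
    ("Nantong", 32.05),
    ("Nanjing", 32.00),
    ("Liyang", 31.27),
    ("Wujiang", 31.08),
]

_SITE_EFFECTS = {
    "Ganyu": 0.2166,
    "Xuzhou": 0.3275,
    "Xuyi": -0.1691,
    "Dongtai": 0.5424,
    "Gaoyou": 0.7057,
    "Yangzhou": 0.2799,
    "Nantong": -0.0369,
    "Nanjing": -0.6264,
    "Liyang": -0.7786,
    "Wujiang": -0.4612,
}


def default_sites() -> list[SiteSpec]:
    """Ten stations with north-south temperature/precipitation gradients."""
    lat_lo, lat_hi = 31.08, 34.50
    sites = []
    for name, lat in _STATIONS:
        frac = (lat_hi - lat) / (lat_hi - lat_lo)  # 0 at north, 1 at south
        sites.append(
            SiteSpec(
                name=name,
                latitude=lat,
                mean_annual_temp=13.0 + 3.0 * frac,
                annual_precip=724.0 + 486.0 * frac,
                warming_slope=0.04 + 0.03 * frac,
            )
        )
    return sites


def default_panel_params(
    sites: Sequence[SiteSpec] | Sequence[str] | None = None,
) -> TruePanelParams:
    """Yield-model coefficients in the regime of the fitted panel model.

    Mean intercept 3.3376 t/ha with site effects spanning roughly
    [-0.78, 0.71]; slope coefficients (-0.1592, -0.1297, 0.0626), AR(1)
    coefficient 0.39 and a residual sd of 0.25 t/ha (a synthetic choice:
    no empirical noise magnitude is available).
    """
    if sites is None:
        names = [name for name, _ in _STATIONS]
    else:
        names = [s.name if isinstance(s, SiteSpec) else str(s) for s in sites]
    effects = list(_SITE_EFFECTS.values())
    intercepts = {
        name: 3.3376 + _SITE_EFFECTS.get(name, effects[i % len(effects)])
        for i, name in enumerate(names)
    }
    return TruePanelParams(
        site_intercepts=intercepts,
        alpha1=-0.1592,
        alpha2=-0.1297,
        alpha3=0.0626,
        rho=0.39,
        error_sd=0.25,
    )


def generate_climate(
    sites: Sequence[SiteSpec],
    start_year: int,
    n_years: int,
    seed: int,
) -> pd.DataFrame:
    """Generate a monthly climate panel: one row per (site, year, month).

    Temperature is the site mean plus a cosine seasonal cycle peaking in
    July, a linear warming trend and Gaussian noise; precipitation is drawn
    per month from a gamma law whose monthly means sum to the site's annual
    total. Bit-identical output for identical (sites, years, seed).
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    names = [s.name for s in sites]
    if len(set(names)) != len(names):
        raise ValueError("duplicate site names")
    if not sites:
        raise ValueError("at least one site is required")

    rng = np.random.default_rng(seed)
    years = np.repeat(np.arange(start_year, start_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)
    n = len(years)

    frames = []
    for site in sites:
        seasonal = site.temp_seasonal_amplitude * np.cos(2.0 * np.pi * (months - 7) / 12.0)
        trend = site.warming_slope * (years - start_year)
        noise = rng.normal(0.0, site.temp_noise_sd, n) if site.temp_noise_sd > 0 else 0.0
        tmean = site.mean_annual_temp + seasonal + trend + noise

        monthly_mean = MONTHLY_PRECIP_WEIGHTS[months - 1] * site.annual_precip
        precip = rng.gamma(site.precip_shape, monthly_mean / site.precip_shape, n)

        frames.append(
            pd.DataFrame(
                {
                    "site": site.name,
                    "latitude": site.latitude,
                    "year": years,
                    "month": months,
                    "tmean_c": tmean,
                    "precip_mm": precip,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_yields(
    spei_covariate: pd.DataFrame,
    params: TruePanelParams,
    seed: int,
    value_col: str = "spei",
) -> pd.DataFrame:
    """Simulate annual yields from the quadratic fixed-effects panel model.

    ``spei_covariate`` is a long DataFrame (site, year, <value_col>) with a
    complete site x year grid. The time index t runs 1..T over the sorted
    distinct years. Returns (site, year, yield_t_ha).
    """
    df = spei_covariate
    for col in ("site", "year", value_col):
        if col not in df.columns:
            raise ValueError(f"covariate frame is missing column {col!r}")
    if df[value_col].isna().any():
        bad = df.loc[df[value_col].isna(), ["site", "year"]].to_records(index=False)
        raise ValueError(f"missing covariate cells: {list(bad)[:5]}")
    wide = df.pivot(index="year", columns="site", values=value_col)
    if wide.isna().any().any():
        raise ValueError("covariate grid is not complete over site x year")
    missing = set(wide.columns) - set(params.site_intercepts)
    if missing:
        raise ValueError(f"no intercept supplied for sites: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    years = wide.index.to_numpy()
    t = np.arange(1, len(years) + 1)

    frames = []
    for site in wide.columns:
        s = wide[site].to_numpy(dtype=float)
        u = _simulate_ar1(rng, len(s), params.rho, params.error_sd)
        y = (
            params.site_intercepts[site]
            + params.alpha1 * s
            + params.alpha2 * s**2
            + params.alpha3 * t
            + u
        )
        frames.append(pd.DataFrame({"site": site, "year": years, "yield_t_ha": y}))
    return pd.concat(frames, ignore_index=True)


def _simulate_ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """AR(1) noise initialized from its stationary distribution."""
    u = np.zeros(n)
    if sd == 0.0:
        return u
    u[0] = rng.normal(0.0, sd / np.sqrt(1.0 - rho**2))
    eps = rng.normal(0.0, sd, n - 1)
    for i in range(1, n):
        u[i] = rho * u[i - 1] + eps[i - 1]
    return u
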