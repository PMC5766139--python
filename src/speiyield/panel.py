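"""Quadratic fixed-effects panel regression of yields on a moisture index.

The model is

    Y_it = beta_i + a1 * s_it + a2 * s_it^2 + a3 * t + u_it,

estimated by least squares with site dummies (LSDV). A within-site
Durbin-Watson statistic screens the residuals for first-order serial
correlation; when it flags autocorrelation the model is re-estimated with
AR(1) errors by iterated Cochrane-Orcutt quasi-differencing.

The concave quadratic in the moisture index s implies a response surface:
a vertex (optimum moisture level), two roots of the pure moisture terms
(loss thresholds), and per-moisture-level yield-response intervals in
kg/ha relative to s = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._exceptions import EstimationError
from .spei import MoistureLevel

__all__ = [
    "PanelFit",
    "fit_panel",
    "durbin_watson",
    "response",
    "optimum_spei",
    "loss_thresholds",
    "response_table",
    "decade_summary",
]

log = logging.getLogger(__name__)

_LEVEL_INTERVALS: list[tuple[MoistureLevel, float, float, bool, bool]] = [
    # (level, lo, hi, lo_closed, hi_closed) on the SPEI axis, Table-6 scheme
    (MoistureLevel.EXTREME_WETTING, 2.0, math.inf, True, False),
    (MoistureLevel.MODERATE_WETTING, 1.0, 2.0, True, False),
    (MoistureLevel.SLIGHT_WETTING, 0.5, 1.0, True, False),
    (MoistureLevel.NORMAL, -0.5, 0.5, False, False),
    (MoistureLevel.SLIGHT_DROUGHT, -1.0, -0.5, False, True),
    (MoistureLevel.MODERATE_DROUGHT, -2.0, -1.0, False, True),
    (MoistureLevel.EXTREME_DROUGHT, -math.inf, -2.0, False, True),
]


@dataclass
class PanelFit:
    """Estimated coefficients and diagnostics of the panel model."""

    site_intercepts: dict[str, float]  # beta_i, t/ha
    alpha1: float  # t/ha per SPEI unit
    alpha2: float  # t/ha per SPEI^2
    alpha3: float  # t/ha per year
    rho: float = 0.0  # AR(1) coefficient (0 when not applied)
    adj_r2: float = float("nan")
    dw: float = float("nan")  # Durbin-Watson of the pre-AR(1) residuals
    n_obs: int = 0
    n_dropped: int = 0
    ar1_applied: bool = False

    @property
    def mean_intercept(self) -> float:
        """Unweighted mean of the site intercepts (beta-bar)."""
        return float(np.mean(list(self.site_intercepts.values())))

    @property
    def fixed_effects(self) -> dict[str, float]:
        """Site effects as deviations from the mean intercept."""
        m = self.mean_intercept
        return {s: b - m for s, b in self.site_intercepts.items()}

    @classmethod
    def from_coefficients(
        cls,
        alpha1: float,
        alpha2: float,
        alpha3: float = 0.0,
        site_intercepts: Mapping[str, float] | None = None,
        rho: float = 0.0,
    ) -> "PanelFit":
        """Build a fit object from externally reported coefficients, for
        evaluating the derived response surface."""
        return cls(
            site_intercepts=dict(site_intercepts or {"all": 0.0}),
            alpha1=float(alpha1),
            alpha2=float(alpha2),
            alpha3=float(alpha3),
            rho=float(rho),
        )


def durbin_watson(residuals_by_site) -> float:
    """Durbin-Watson statistic with differences taken within sites only.

    ``residuals_by_site`` is a mapping site -> time-ordered residual array
    (or any iterable of arrays). dw = sum of squared within-site first
    differences over the total residual sum of squares; values near 2
    indicate no first-order serial correlation.
    """
    groups = (
        list(residuals_by_site.values())
        if isinstance(residuals_by_site, Mapping)
        else list(residuals_by_site)
    )
    num = 0.0
    den = 0.0
    any_pair = False
    for g in groups:
        e = np.asarray(g, dtype=float)
        if len(e) >= 2:
            any_pair = True
            num += float(np.sum(np.diff(e) ** 2))
        den += float(np.sum(e**2))
    if not any_pair:
        raise ValueError("Durbin-Watson requires at least 2 residuals in some site")
    if den == 0.0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    return num / den


def _design(df: pd.DataFrame, sites: list[str], value_col: str) -> np.ndarray:
    dummies = np.stack([(df["site"] == s).to_numpy(float) for s in sites], axis=1)
    s = df[value_col].to_numpy(float)
    t = df["t"].to_numpy(float)
    return np.column_stack([dummies, s, s**2, t])


def fit_panel(
    yields: pd.DataFrame,
    covariate: pd.DataFrame,
    value_col: str = "spei",
    ar1: str = "auto",
    dw_bounds: tuple[float, float] = (1.5, 2.5),
    max_iter: int = 50,
    tol: float = 1e-6,
) -> PanelFit:
    """Estimate the fixed-effects quadratic panel model by LSDV.

    ``yields`` has columns (site, year, yield_t_ha); ``covariate`` has
    (site, year, <value_col>). Rows without a matching covariate (or with
    missing values) are dropped with a logged count. The time index t runs
    1..T over the sorted distinct years of the merged panel.

    ``ar1`` is "auto" (apply AR(1) when the Durbin-Watson statistic falls
    outside ``dw_bounds``), "on" or "off". AR(1) estimation is iterated
    Cochrane-Orcutt: rho from the pooled within-site lagged residual
    regression, quasi-differencing of all regressors including the site
    dummies (first observation per site dropped), refit to convergence.
    """
    if ar1 not in ("auto", "on", "off"):
        raise ValueError("ar1 must be one of 'auto', 'on', 'off'")
    df = yields.merge(covariate[["site", "year", value_col]], on=["site", "year"], how="left")
    n_before = len(df)
    df = df.dropna(subset=["yield_t_ha", value_col]).copy()
    n_dropped = n_before - len(df)
    if n_dropped:
        log.info("fit_panel: dropped %d unmatched/missing panel cells", n_dropped)

    sites = sorted(df["site"].unique())
    if len(sites) < 2:
        raise ValueError("panel estimation requires >= 2 sites")
    counts = df.groupby("site")["year"].count()
    if (counts < 5).any():
        raise ValueError("panel estimation requires >= 5 years per site")

    years = np.sort(df["year"].unique())
    year_to_t = {int(y): i + 1 for i, y in enumerate(years)}
    df["t"] = df["year"].map(year_to_t)
    df = df.sort_values(["site", "year"]).reset_index(drop=True)

    if df[value_col].std() == 0.0:
        raise EstimationError("constant covariate: quadratic design is rank deficient")

    X = _design(df, sites, value_col)
    y = df["yield_t_ha"].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("rank-deficient design matrix")

    ols = sm.OLS(y, X).fit()
    beta = ols.params

    site_codes = df["site"].to_numpy()
    resid_groups = lambda e: {s: e[site_codes == s] for s in sites}
    dw = durbin_watson(resid_groups(y - X @ beta))

    apply_ar1 = ar1 == "on" or (ar1 == "auto" and not dw_bounds[0] <= dw <= dw_bounds[1])

    rho = 0.0
    if apply_ar1:
        rho_prev = 0.0
        Xstar, ystar = X, y
        for _ in range(max_iter):
            e = y - X @ beta
            num = den = 0.0
            for s in sites:
                es = e[site_codes == s]
                num += float(np.sum(es[1:] * es[:-1]))
                den += float(np.sum(es[:-1] ** 2))
            if den == 0.0:
                rho = 0.0
                break
            rho = float(np.clip(num / den, -0.99, 0.99))
            Xs_parts, ys_parts = [], []
            for s in sites:
                m = site_codes == s
                Xs_parts.append(X[m][1:] - rho * X[m][:-1])
                ys_parts.append(y[m][1:] - rho * y[m][:-1])
            Xstar = np.vstack(Xs_parts)
            ystar = np.concatenate(ys_parts)
            final = sm.OLS(ystar, Xstar).fit()
            beta = final.params
            if abs(rho - rho_prev) < tol:
                break
            rho_prev = rho
        adj_r2 = _adjusted_r2(ystar, Xstar @ beta, X.shape[1])
    else:
        adj_r2 = _adjusted_r2(y, X @ beta, X.shape[1])

    k = len(sites)
    return PanelFit(
        site_intercepts={s: float(beta[i]) for i, s in enumerate(sites)},
        alpha1=float(beta[k]),
        alpha2=float(beta[k + 1]),
        alpha3=float(beta[k + 2]),
        rho=rho,
        adj_r2=adj_r2,
        dw=dw,
        n_obs=len(df),
        n_dropped=n_dropped,
        ar1_applied=bool(apply_ar1),
    )


def _adjusted_r2(y: np.ndarray, yhat: np.ndarray, p: int) -> float:
    n = len(y)
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0 or n <= p:
        return float("nan")
    r2 = 1.0 - ssr / sst
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p)


def response(s, fit: PanelFit) -> np.ndarray | float:
    """Yield response in kg/ha relative to s = 0: 1000 (a1 s + a2 s^2)."""
    sv = np.asarray(s, dtype=float)
    out = 1000.0 * (fit.alpha1 * sv + fit.alpha2 * sv**2)
    return float(out) if out.ndim == 0 else out


def optimum_spei(fit: PanelFit) -> float:
    """Vertex of the concave response parabola, -a1/(2 a2)."""
    if not fit.alpha2 < 0:
        raise EstimationError("no interior optimum: quadratic term is not negative")
    return -fit.alpha1 / (2.0 * fit.alpha2)


def loss_thresholds(fit: PanelFit) -> tuple[float, float]:
    """The two roots of a1 s + a2 s^2 = 0: zero response at s = 0 and
    s = -a1/a2; outside the bracket the response is a yield loss."""
    if fit.alpha2 == 0.0:
        raise EstimationError("degenerate response: single root at 0")
    if not fit.alpha2 < 0:
        raise EstimationError("response is not concave")
    other = -fit.alpha1 / fit.alpha2
    return tuple(sorted((0.0, other)))


def _interval_response(
    fit: PanelFit, lo: float, hi: float, lo_closed: bool, hi_closed: bool
) -> tuple[float, bool, float, bool]:
    """Response interval (value, closed) bounds over one SPEI interval.

    Endpoint responses provide the candidate bounds; when the parabola's
    vertex falls strictly inside the interval, the upper bound is the
    vertex response (attained, hence closed).
    """
    candidates: list[tuple[float, bool]] = []
    for s, closed in ((lo, lo_closed), (hi, hi_closed)):
        if math.isinf(s):
            candidates.append((-math.inf, False))
        else:
            candidates.append((response(s, fit), closed))
    v = optimum_spei(fit)
    if lo < v < hi:
        candidates.append((response(v, fit), True))
    lo_r = min(candidates, key=lambda c: c[0])
    hi_r = max(candidates, key=lambda c: c[0])
    return lo_r[0], lo_r[1], hi_r[0], hi_r[1]


def _fmt_interval(lo: float, lo_c: bool, hi: float, hi_c: bool, nd: int) -> str:
    if math.isinf(lo):
        return f"{'<=' if hi_c else '<'}{hi:.{nd}f}"
    if math.isinf(hi):
        return f"{'>=' if lo_c else '>'}{lo:.{nd}f}"
    return f"{'[' if lo_c else '('}{lo:.{nd}f}, {hi:.{nd}f}{']' if hi_c else ')'}"


def response_table(fit: PanelFit) -> pd.DataFrame:
    """Per-moisture-level yield-response intervals in kg/ha.

    One row per level with the SPEI interval, the numeric response bounds
    and printable interval strings (responses to 1 decimal, matching the
    reporting precision of the thresholds/derived scalars)."""
    if not fit.alpha2 < 0:
        raise EstimationError("response table requires a concave response")
    rows = []
    for level, lo, hi, lo_c, hi_c in _LEVEL_INTERVALS:
        r_lo, r_lo_c, r_hi, r_hi_c = _interval_response(fit, lo, hi, lo_c, hi_c)
        rows.append(
            {
                "level": level.value,
                "spei_lo": lo,
                "spei_hi": hi,
                "spei_interval": _fmt_interval(lo, lo_c, hi, hi_c, 1),
                "response_lo_kg_ha": r_lo,
                "response_hi_kg_ha": r_hi,
                "response_interval": _fmt_interval(r_lo, r_lo_c, r_hi, r_hi_c, 1),
            }
        )
    return pd.DataFrame(rows)


def decade_summary(
    values: pd.DataFrame,
    periods: Sequence[tuple[int, int]],
    fit: PanelFit | None = None,
    value_col: str = "spei",
) -> pd.DataFrame:
    """Mean of a per-(site, year) series over year ranges, optionally with
    the fitted yield response evaluated at each period mean.

    ``periods`` are inclusive (start, end) ranges and must not overlap.
    """
    spans = sorted(periods)
    for (a1_, b1), (a2_, _) in zip(spans, spans[1:]):
        if a2_ <= b1:
            raise ValueError("periods must not overlap")
    rows = []
    for start, end in periods:
        sel = values[(values["year"] >= start) & (values["year"] <= end)]
        if sel.empty:
            raise ValueError(f"period {start}-{end} contains no observations")
        mean = float(sel[value_col].mean())
        row = {"period": f"{start}-{end}", "mean": mean, "n": len(sel)}
        if fit is not None:
            row["response_kg_ha"] = response(mean, fit)
        rows.append(row)
    return pd.DataFrame(rows)
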