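"""Growth-stage SPEI covariates and detrended yield-moisture correlations.

The winter-wheat season runs October through June; the growing season of
harvest year y spans Oct(y-1)..Jun(y). Stage covariates are arithmetic
means of the monthly SPEI values (at the series' scale) over the stage's
months. Yields and covariates are both detrended by first-order
differencing before Pearson correlation, removing technological and other
slow trends so the residual co-variation reflects climate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "StageDefinition",
    "LinkageTable",
    "DEFAULT_STAGES",
    "season_covariate",
    "first_difference",
    "correlate",
    "significance_stars",
    "linkage_tables",
]


@dataclass(frozen=True)
class StageDefinition:
    """A growth stage as (year_offset, calendar_month) pairs.

    ``year_offset`` is relative to the harvest year: Oct-Dec of the sowing
    calendar year carry offset -1, Jan-Jun of the harvest calendar year
    carry offset 0.
    """

    name: str
    months: tuple[tuple[int, int], ...]


# S1 sowing/seedling (Oct-Nov), S2 over-wintering (Dec-Feb), S3 late growth
# (Apr-Jun); March falls in no stage. full_season spans Oct-Jun (9 months).
DEFAULT_STAGES: dict[str, StageDefinition] = {
    "S1": StageDefinition("S1", ((-1, 10), (-1, 11))),
    "S2": StageDefinition("S2", ((-1, 12), (0, 1), (0, 2))),
    "S3": StageDefinition("S3", ((0, 4), (0, 5), (0, 6))),
    "full_season": StageDefinition(
        "full_season",
        ((-1, 10), (-1, 11), (-1, 12), (0, 1), (0, 2), (0, 3), (0, 4), (0, 5), (0, 6)),
    ),
}


def season_covariate(
    spei: pd.DataFrame,
    stage: StageDefinition | str,
    harvest_years: Sequence[int] | None = None,
    value_col: str = "spei",
) -> pd.DataFrame:
    """Per-(site, harvest_year) mean SPEI over a growth stage's months.

    ``spei`` is a long DataFrame (site, year, month, <value_col>) at a
    single time scale. When ``harvest_years`` is omitted, the covariate is
    computed for every harvest year whose stage months are all present and
    defined; when given explicitly, any missing cell raises an error
    listing the affected (site, harvest_year, month) cells.
    """
    if isinstance(stage, str):
        stage = DEFAULT_STAGES[stage]
    lookup = {
        (s, int(y), int(m)): v
        for s, y, m, v in zip(
            spei["site"], spei["year"], spei["month"], spei[value_col]
        )
    }
    sites = list(dict.fromkeys(spei["site"]))
    if harvest_years is None:
        years = sorted(set(int(y) for y in spei["year"]))
        candidates = range(min(years), max(years) + 2)
        explicit = False
    else:
        candidates = [int(y) for y in harvest_years]
        explicit = True

    rows, missing = [], []
    for site in sites:
        for hy in candidates:
            vals = []
            for off, m in stage.months:
                v = lookup.get((site, hy + off, m), np.nan)
                if not np.isfinite(v):
                    missing.append((site, hy, m))
                    vals = None
                    break
                vals.append(v)
            if vals is not None:
                rows.append({"site": site, "year": hy, value_col: float(np.mean(vals))})
            elif not explicit:
                missing.pop()  # silently out of coverage in auto mode
    if explicit and missing:
        raise ValueError(
            f"stage {stage.name}: missing SPEI for cells (site, harvest_year, month): "
            f"{missing[:10]}"
        )
    return pd.DataFrame(rows, columns=["site", "year", value_col])


def first_difference(series) -> np.ndarray:
    """First-order differences x_{t+1} - x_t; output length n - 1."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("first difference requires a 1-d series with n >= 2")
    return np.diff(x)


def significance_stars(p: float) -> str:
    """Annotation: '**' below 1%, '*' below 5%, empty otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate(detrended_yield, detrended_covariate) -> tuple[float, float, str]:
    """Pearson correlation with two-sided p (t-distribution, n-2 df)."""
    y = np.asarray(detrended_yield, dtype=float)
    x = np.asarray(detrended_covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("series must have equal length")
    if len(y) < 4:
        raise ValueError("correlation requires n >= 4")
    if np.std(y) == 0.0 or np.std(x) == 0.0:
        raise ValueError("undefined correlation: zero-variance input")
    r, p = pearsonr(y, x)
    return float(r), float(p), significance_stars(float(p))


@dataclass
class LinkageTable:
    """Site x covariate table of detrended Pearson correlations."""

    data: pd.DataFrame  # tidy: site, covariate, r, p, stars, n

    def pivot(self, value: str = "r") -> pd.DataFrame:
        cols = list(dict.fromkeys(self.data["covariate"]))
        return self.data.pivot(index="site", columns="covariate", values=value)[cols]

    def formatted(self) -> pd.DataFrame:
        """Cells like '-0.36*' mirroring the conventional presentation."""
        df = self.data.assign(
            cell=lambda d: d["r"].map(lambda r: f"{r:.2f}") + d["stars"]
        )
        cols = list(dict.fromkeys(df["covariate"]))
        return df.pivot(index="site", columns="covariate", values="cell")[cols]


def _common_run(years_a: Iterable[int], years_b: Iterable[int]) -> list[int]:
    common = sorted(set(years_a) & set(years_b))
    if not common:
        return []
    if any(b - a != 1 for a, b in zip(common, common[1:])):
        raise ValueError("overlapping years are not consecutive; cannot difference")
    return common


def linkage_tables(
    yields: pd.DataFrame,
    spei_by_scale: Mapping[int, pd.DataFrame] | pd.DataFrame,
    season_scales: Sequence[int] = (1, 3, 6, 9),
    stage_scales: Sequence[int] = (1, 3),
    stages: Mapping[str, StageDefinition] = DEFAULT_STAGES,
) -> tuple[LinkageTable, LinkageTable]:
    """Correlation tables between detrended yields and detrended SPEI.

    Returns two tables: full-season covariates at ``season_scales``
    (columns SPEI_k) and stage covariates at ``stage_scales`` for stages
    S1/S2/S3 (columns SPEI_k_Sj). Requires at least 5 overlapping seasons
    per site.
    """
    if isinstance(spei_by_scale, pd.DataFrame):
        spei_by_scale = {
            int(k): g.drop(columns=["scale_k"])
            for k, g in spei_by_scale.groupby("scale_k")
        }

    def table(covariates: list[tuple[str, int, StageDefinition]]) -> LinkageTable:
        rows = []
        for label, k, stage in covariates:
            cov = season_covariate(spei_by_scale[k], stage)
            for site, gy in yields.groupby("site", sort=False):
                gc = cov[cov["site"] == site]
                common = _common_run(gy["year"], gc["year"])
                if len(common) < 5:
                    raise ValueError(
                        f"site {site!r}, covariate {label}: only {len(common)} "
                        "overlapping seasons (need >= 5)"
                    )
                ys = gy.set_index("year").loc[common, "yield_t_ha"].to_numpy()
                cs = gc.set_index("year").loc[common, "spei"].to_numpy()
                r, p, stars = correlate(first_difference(ys), first_difference(cs))
                rows.append(
                    {
                        "site": site,
                        "covariate": label,
                        "r": r,
                        "p": p,
                        "stars": stars,
                        "n": len(common) - 1,
                    }
                )
        return LinkageTable(pd.DataFrame(rows))

    season = [(f"SPEI_{k}", k, stages["full_season"]) for k in season_scales]
    stage_list = [
        (f"SPEI_{k}_{name}", k, stages[name])
        for k in stage_scales
        for name in ("S1", "S2", "S3")
    ]
    return table(season), table(stage_list)
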