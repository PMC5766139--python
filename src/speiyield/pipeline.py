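"""End-to-end pipeline: climate panel -> SPEI -> trends -> linkage -> panel
model -> derived response surface, with a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import (
    sha256_file,
    validate_climate,
    validate_yields,
    write_csv,
)
from .linkage import linkage_tables, season_covariate
from .panel import (
    decade_summary,
    fit_panel,
    loss_thresholds,
    optimum_spei,
    response_table,
)
from .spei import compute_spei
from .trends import trend_suite

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)

# Months of the crop season (Oct(y-1)..Jun(y)) used for the season summaries.
_SEASON_MONTHS = [10, 11, 12, 1, 2, 3, 4, 5, 6]


def _season_annual(climate: pd.DataFrame, col: str, how: str) -> pd.DataFrame:
    """Aggregate a monthly climate column over each site's crop season,
    labeled by harvest year."""
    df = climate.copy()
    df["harvest_year"] = df["year"] + df["month"].isin([10, 11, 12]).astype(int)
    df = df[df["month"].isin(_SEASON_MONTHS)]
    full = df.groupby(["site", "harvest_year"])["month"].transform("count") == len(
        _SEASON_MONTHS
    )
    df = df[full]
    agg = getattr(df.groupby(["site", "harvest_year"])[col], how)().reset_index()
    return agg.rename(columns={"harvest_year": "year", col: "value"})


def run_pipeline(
    config: PipelineConfig,
    climate: pd.DataFrame | str | Path,
    yields: pd.DataFrame | str | Path,
    out_dir: str | Path,
) -> dict:
    """Run every analysis stage and write the outputs plus a manifest.

    Outputs (CSV unless noted): spei, trends, linkage_season,
    linkage_stages, panel_fit.json, response_table, decade_summary,
    manifest.json. Identical inputs + config produce identical manifests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    input_hashes = {}
    if not isinstance(climate, pd.DataFrame):
        input_hashes["climate"] = sha256_file(climate)
        climate = pd.read_csv(climate)
    if not isinstance(yields, pd.DataFrame):
        input_hashes["yields"] = sha256_file(yields)
        yields = pd.read_csv(yields)
    climate = validate_climate(climate)
    yields = validate_yields(yields)

    # SPEI at every configured scale.
    spei = compute_spei(
        climate,
        scales=config.scales,
        calibration=config.calibration,
        pwm_method=config.pwm_method,
    )
    paths = {"spei": write_csv(spei, out / "spei.csv")}

    # Trend suite over crop-season aggregates: mean temperature, total
    # precipitation, and mean 1-month SPEI per harvest year.
    trend_inputs = {
        "season_mean_temp": _season_annual(climate, "tmean_c", "mean"),
        "season_total_precip": _season_annual(climate, "precip_mm", "sum"),
    }
    spei1 = spei[spei["scale_k"] == min(config.scales)]
    cov1 = season_covariate(spei1, "full_season")
    trend_inputs["season_mean_spei"] = cov1.rename(columns={"spei": "value"})
    trend_frames = []
    for label, data in trend_inputs.items():
        res = trend_suite(data, value_col="value", time_col="year", alpha=config.alpha)
        res.insert(0, "variable", label)
        trend_frames.append(res)
    trends = pd.concat(trend_frames, ignore_index=True)
    paths["trends"] = write_csv(trends, out / "trends.csv")

    # Detrended correlation tables.
    season_tbl, stage_tbl = linkage_tables(
        yields,
        spei,
        season_scales=config.scales,
        stage_scales=config.stage_scales,
        stages=config.stages,
    )
    paths["linkage_season"] = write_csv(season_tbl.data, out / "linkage_season.csv")
    paths["linkage_stages"] = write_csv(stage_tbl.data, out / "linkage_stages.csv")

    # Panel model on the configured stage covariate (default SPEI_3_S3).
    spei_k = spei[spei["scale_k"] == config.panel_scale]
    covariate = season_covariate(spei_k, config.stages[config.panel_stage])
    fit = fit_panel(
        yields, covariate, ar1=config.ar1, dw_bounds=config.dw_bounds
    )
    fit_payload = {
        "site_intercepts": fit.site_intercepts,
        "fixed_effects": fit.fixed_effects,
        "mean_intercept": fit.mean_intercept,
        "alpha1": fit.alpha1,
        "alpha2": fit.alpha2,
        "alpha3": fit.alpha3,
        "rho": fit.rho,
        "adj_r2": fit.adj_r2,
        "dw": fit.dw,
        "n_obs": fit.n_obs,
        "n_dropped": fit.n_dropped,
        "ar1_applied": fit.ar1_applied,
        "optimum_spei": round(optimum_spei(fit), 2),
        "loss_thresholds": [round(v, 2) for v in loss_thresholds(fit)],
    }
    fit_path = out / "panel_fit.json"
    fit_path.write_text(json.dumps(fit_payload, indent=2, sort_keys=True) + "\n")
    paths["panel_fit"] = fit_path

    paths["response_table"] = write_csv(response_table(fit), out / "response_table.csv")
    paths["decade_summary"] = write_csv(
        decade_summary(covariate, config.periods, fit=fit), out / "decade_summary.csv"
    )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": input_hashes,
        "outputs": {k: {"path": p.name, "sha256": sha256_file(p)} for k, p in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
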