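"""Pipeline configuration, parseable from a single YAML document.

Defaults reproduce the study settings: scales 1/3/6/9 months, winter-wheat
stages S1/S2/S3, significance level 0.05, panel covariate = 3-month SPEI
averaged over the late growth stage, decade periods 1980-1989 / 1990-1999 /
2000-2014.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .linkage import DEFAULT_STAGES, StageDefinition

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    scales: list[int] = field(default_factory=lambda: [1, 3, 6, 9])
    stage_scales: list[int] = field(default_factory=lambda: [1, 3])
    stages: dict[str, StageDefinition] = field(default_factory=lambda: dict(DEFAULT_STAGES))
    calibration: tuple[int, int] | None = None
    alpha: float = 0.05
    panel_scale: int = 3
    panel_stage: str = "S3"
    ar1: str = "auto"
    dw_bounds: tuple[float, float] = (1.5, 2.5)
    periods: list[tuple[int, int]] = field(
        default_factory=lambda: [(1980, 1989), (1990, 1999), (2000, 2014)]
    )
    pwm_method: str = "unbiased"
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        cfg = cls()
        simple = {
            "scales", "stage_scales", "alpha", "panel_scale", "panel_stage",
            "ar1", "pwm_method", "seed",
        }
        for key, value in data.items():
            if key in simple:
                setattr(cfg, key, value)
            elif key == "calibration":
                cfg.calibration = None if value is None else (int(value[0]), int(value[1]))
            elif key == "dw_bounds":
                cfg.dw_bounds = (float(value[0]), float(value[1]))
            elif key == "periods":
                cfg.periods = [(int(a), int(b)) for a, b in value]
            elif key == "stages":
                cfg.stages = dict(DEFAULT_STAGES)
                for name, months in value.items():
                    cfg.stages[name] = StageDefinition(
                        name, tuple((int(o), int(m)) for o, m in months)
                    )
            else:
                raise ValueError(f"unknown configuration key: {key!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return {
            "scales": list(self.scales),
            "stage_scales": list(self.stage_scales),
            "stages": {
                name: [list(m) for m in stage.months] for name, stage in self.stages.items()
            },
            "calibration": list(self.calibration) if self.calibration else None,
            "alpha": self.alpha,
            "panel_scale": self.panel_scale,
            "panel_stage": self.panel_stage,
            "ar1": self.ar1,
            "dw_bounds": list(self.dw_bounds),
            "periods": [list(p) for p in self.periods],
            "pwm_method": self.pwm_method,
            "seed": self.seed,
        }
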