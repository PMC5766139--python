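"""Readers and writers for the pipeline's long-format CSV interchange files.

Readers validate schema and completeness and raise ``ValidationError``
naming the offending file/site/row; nothing is silently imputed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import ValidationError

__all__ = [
    "read_climate",
    "read_yields",
    "write_csv",
    "sha256_file",
]

CLIMATE_COLUMNS = ["site", "latitude", "year", "month", "tmean_c", "precip_mm"]
YIELD_COLUMNS = ["site", "year", "yield_t_ha"]


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def validate_climate(df: pd.DataFrame, name: str = "climate panel") -> pd.DataFrame:
    for col in ("latitude", "year", "month", "tmean_c", "precip_mm"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(f"{name}: missing value in column {col!r} at row {bad[0]}")
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        row = df.index[(df["month"] < 1) | (df["month"] > 12)][0]
        raise ValidationError(f"{name}: month out of range at row {row}")
    if (df["precip_mm"] < 0).any():
        row = df.index[df["precip_mm"] < 0][0]
        raise ValidationError(f"{name}: negative precipitation at row {row}")
    for site, g in df.groupby("site"):
        g = g.sort_values(["year", "month"])
        code = g["year"].to_numpy(int) * 12 + g["month"].to_numpy(int) - 1
        if len(np.unique(code)) != len(code):
            raise ValidationError(f"{name}: duplicate month for site {site!r}")
        gaps = np.flatnonzero(np.diff(code) != 1)
        if len(gaps):
            miss = code[gaps[0]] + 1
            raise ValidationError(
                f"{name}: site {site!r} is missing month "
                f"{miss // 12}-{miss % 12 + 1:02d}"
            )
    return df


def validate_yields(df: pd.DataFrame, name: str = "yield panel") -> pd.DataFrame:
    for col in ("year", "yield_t_ha"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(f"{name}: missing value in column {col!r} at row {bad[0]}")
    if (df["yield_t_ha"] <= 0).any():
        row = df.index[df["yield_t_ha"] <= 0][0]
        raise ValidationError(f"{name}: non-positive yield at row {row}")
    dup = df.duplicated(subset=["site", "year"])
    if dup.any():
        raise ValidationError(f"{name}: duplicate (site, year) at row {df.index[dup][0]}")
    return df


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read and validate a monthly climate panel CSV."""
    return validate_climate(_read(path, CLIMATE_COLUMNS), name=str(path))


def read_yields(path: str | Path) -> pd.DataFrame:
    """Read and validate an annual yield panel CSV."""
    return validate_yields(_read(path, YIELD_COLUMNS), name=str(path))


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame with full float precision (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
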