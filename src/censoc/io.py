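"""Tabular text readers/writers for weather, SOC and paired-evaluation files.

All formats are comma-separated with a header row; SOC stocks are Mg/ha
(the unit is part of the column name and enforced on read), weather columns
are year,month,tmax,tmin,precip,irrigation.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .drivers import WEATHER_COLUMNS

__all__ = [
    "read_weather_table",
    "write_weather_table",
    "read_soc_table",
    "write_soc_table",
    "read_paired_table",
    "write_paired_table",
]

SOC_COLUMNS = ["year", "stock_Mg_ha"]
PAIRED_COLUMNS = ["year", "measured", "simulated"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; header must "
                         f"contain {required}")
    for i, (_, row) in enumerate(df[required].iterrows(), start=2):
        if row.isna().any():
            raise ValueError(f"{path}: malformed row at line {i}: {row.to_dict()}")
    return df


def read_weather_table(path) -> pd.DataFrame:
    df = _read_csv(path, [c for c in WEATHER_COLUMNS if c != "irrigation"])
    if "irrigation" not in df.columns:
        df["irrigation"] = 0.0
    return df[WEATHER_COLUMNS].astype(float).astype({"year": int, "month": int})


def write_weather_table(df: pd.DataFrame, path) -> None:
    df[WEATHER_COLUMNS].to_csv(path, index=False)


def read_soc_table(path) -> pd.DataFrame:
    """Annual SOC stocks; duplicate years are rejected."""
    df = _read_csv(path, SOC_COLUMNS)
    dup = df["year"][df["year"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate year(s) {sorted(set(int(d) for d in dup))}")
    return df[SOC_COLUMNS].astype({"year": int, "stock_Mg_ha": float})


def write_soc_table(df: pd.DataFrame, path) -> None:
    df[SOC_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def read_paired_table(path) -> pd.DataFrame:
    df = _read_csv(path, PAIRED_COLUMNS)
    return df[PAIRED_COLUMNS].astype({"year": int, "measured": float, "simulated": float})


def write_paired_table(df: pd.DataFrame, path) -> None:
    df[PAIRED_COLUMNS].to_csv(path, index=False, float_format="%.10g")
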