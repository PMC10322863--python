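"""CSV readers/writers and structured configuration.

Half-hourly flux tables use the site's standard column abbreviations
(NEE, H, LE, u*, SW_IN, PPFD, TA, RH, Prec, SWC_50, ...). Timestamps mark
the end of each 30-min interval in local standard time (no DST); missing
values are empty fields in CSV and NaN in memory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fluxlegacy.synthetic import SimConfig, LloydTaylorTruth, LightResponseTruth, PhenoTruth

#: in-memory name -> CSV header
FLUX_CSV_NAMES = {"ustar": "u*"}
FLUX_REQUIRED = ("timestamp", "NEE", "ustar", "SW_IN", "PPFD", "TA", "RH",
                 "Prec", "SWC_50")
CLIMATE_REQUIRED = ("date", "precip", "tmin", "tmax", "tmean", "latitude")

_HEADER_NOTE = ("# timestamps: end of 30-min interval, local standard time; "
                "missing values empty\n")


def write_flux_csv(table: pd.DataFrame, path):
    """Write a half-hourly flux table (u* header, empty-field missing)."""
    out = table.rename(columns=FLUX_CSV_NAMES)
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE)
        out.to_csv(fh, index=False, na_rep="")


def read_flux_csv(path) -> pd.DataFrame:
    """Read and validate a half-hourly flux table."""
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns={v: k for k, v in FLUX_CSV_NAMES.items()})
    missing = [c for c in FLUX_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"flux table missing required columns: {missing}")
    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as err:
        bad = None
        parsed = pd.to_datetime(df["timestamp"], errors="coerce")
        bad_rows = np.flatnonzero(parsed.isna().to_numpy())
        if len(bad_rows):
            bad = bad_rows[0] + 2  # 1-based + header line
        raise ValueError(f"malformed timestamp (first bad CSV line: {bad})") from err
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("timestamps must be strictly increasing without duplicates")
    df["timestamp"] = ts
    rh = df["RH"].dropna()
    if ((rh < 0) | (rh > 100)).any():
        raise ValueError("RH outside [0, 100]")
    if (df["PPFD"].dropna() < 0).any():
        raise ValueError("negative PPFD")
    return df


def write_climate_csv(table: pd.DataFrame, path):
    table.to_csv(path, index=False, na_rep="")


def read_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLIMATE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"climate table missing required columns: {missing}")
    df["date"] = pd.to_datetime(df["date"])
    if (df["precip"].dropna() < 0).any():
        raise ValueError("negative precipitation")
    if (df["tmin"] > df["tmean"]).any() or (df["tmean"] > df["tmax"]).any():
        raise ValueError("temperature ordering violated (tmin <= tmean <= tmax)")
    return df


def write_gcc_csv(table: pd.DataFrame, path):
    table.to_csv(path, index=False, na_rep="")


def read_gcc_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" not in df.columns or "gcc" not in df.columns:
        raise ValueError("greenness table needs columns date, gcc")
    df["date"] = pd.to_datetime(df["date"])
    return df


def config_to_yaml(config: SimConfig, path):
    """Write a simulation configuration as YAML (keys mirror SimConfig)."""
    d = dataclasses.asdict(config)
    d["years"] = list(d["years"])
    d["drought_years"] = {int(k): list(v) for k, v in d["drought_years"].items()}
    d["legacy_deficit_ramp"] = list(d["legacy_deficit_ramp"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    """Read a simulation configuration; unknown keys are an error."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    valid = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; "
                         f"valid keys: {sorted(valid)}")
    for name, cls in (("lt_params", LloydTaylorTruth),
                      ("lr_params", LightResponseTruth),
                      ("pheno_params", PhenoTruth)):
        if name in d and isinstance(d[name], dict):
            d[name] = cls(**d[name])
    if "years" in d:
        d["years"] = tuple(d["years"])
    if "drought_years" in d:
        d["drought_years"] = {int(k): tuple(v) for k, v in d["drought_years"].items()}
    if "legacy_deficit_ramp" in d:
        d["legacy_deficit_ramp"] = tuple(d["legacy_deficit_ramp"])
    return SimConfig(**d)
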