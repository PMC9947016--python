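"""CSV schemas and readers/writers for datasets and results.

Schemas (column names are load-bearing and validated):

* viability:   c_dox0_uM, c_dex0_uM, time_h, replicate, viability_pct
* degradation: drug, time_h, conc_uM
* pk:          dose_mg_per_m2, bsa_m2, time_h, conc_mg_L
* profile:     drug_or_condition, time_h, value, unit  (generic curve export)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fit import ViabilityDataset

__all__ = [
    "read_viability_csv",
    "write_viability_csv",
    "read_degradation_csv",
    "write_degradation_csv",
    "read_pk_csv",
    "write_pk_csv",
    "write_profile_csv",
]

VIABILITY_COLUMNS = list(ViabilityDataset.REQUIRED)
DEGRADATION_COLUMNS = ["drug", "time_h", "conc_uM"]
PK_COLUMNS = ["dose_mg_per_m2", "bsa_m2", "time_h", "conc_mg_L"]


def _validate(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} CSV is missing columns {missing}; expected {columns}")
    return df[columns]


def read_viability_csv(path: str | Path) -> ViabilityDataset:
    df = _validate(pd.read_csv(path), VIABILITY_COLUMNS, "viability")
    return ViabilityDataset(df)


def write_viability_csv(data: ViabilityDataset, path: str | Path) -> None:
    data.df[VIABILITY_COLUMNS].to_csv(path, index=False)


def read_degradation_csv(path: str | Path) -> pd.DataFrame:
    df = _validate(pd.read_csv(path), DEGRADATION_COLUMNS, "degradation")
    if (df["conc_uM"] <= 0).any():
        raise ValueError("degradation concentrations must be > 0")
    return df


def write_degradation_csv(df: pd.DataFrame, path: str | Path) -> None:
    _validate(df, DEGRADATION_COLUMNS, "degradation").to_csv(path, index=False)


def read_pk_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "bsa_m2" not in df.columns:
        df["bsa_m2"] = 1.8
    df = _validate(df, PK_COLUMNS, "pk")
    if (df["conc_mg_L"] < 0).any():
        raise ValueError("PK concentrations must be >= 0")
    return df


def write_pk_csv(df: pd.DataFrame, path: str | Path) -> None:
    _validate(df, PK_COLUMNS, "pk").to_csv(path, index=False)


def write_profile_csv(labels, times, values, unit: str, path: str | Path) -> None:
    """Write one or more named curves in long form."""
    frames = []
    for label, v in zip(labels, np.atleast_2d(values)):
        frames.append(pd.DataFrame({
            "drug_or_condition": label,
            "time_h": np.asarray(times, float),
            "value": np.asarray(v, float),
            "unit": unit,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
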