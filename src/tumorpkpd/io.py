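"""CSV / JSON dialects for cohort measurements, PK series and fit results."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError

#: The six experimental arms of the mouse studies.
ARMS = (
    "control_gcv_only",
    "fd_aavp_gcv",
    "csstresac_aavp_gcv",
    "vehicle",
    "control_peptide",
    "soluble_csstresac",
)

COHORT_COLUMNS = ["arm", "subject_id", "day", "volume_mm3"]
SUMMARY_COLUMNS = ["arm", "day", "mean_mm3", "sd_mm3"]
PK_COLUMNS = ["day", "concentration"]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort-measurement contract; returns the frame untouched.

    Columns ``arm, subject_id, day, volume_mm3``; non-negative days/volumes;
    unique (arm, subject, day); known arm labels.
    """
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort frame missing columns {missing}")
    unknown = set(df["arm"].unique()) - set(ARMS)
    if unknown:
        raise ConfigurationError(f"unknown arm labels {sorted(unknown)}")
    if (df["volume_mm3"] < 0).any() or (df["day"] < 0).any():
        raise ConfigurationError("days and volumes must be non-negative")
    if df.duplicated(subset=["arm", "subject_id", "day"]).any():
        raise ConfigurationError("(arm, subject_id, day) must be unique")
    return df


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # surface the offending line
        raise ConfigurationError(f"{path}: malformed CSV: {exc}") from exc
    return validate_cohort(df)


def write_cohort_csv(path: str | Path, df: pd.DataFrame) -> None:
    validate_cohort(df)[COHORT_COLUMNS].to_csv(path, index=False)


def summarize_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(arm, day) mean and SD of tumor volume."""
    g = (
        validate_cohort(df)
        .groupby(["arm", "day"], as_index=False)["volume_mm3"]
        .agg(mean_mm3="mean", sd_mm3="std")
    )
    return g[SUMMARY_COLUMNS]


def arm_means(df: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Mean volume per day for one arm, sorted by day."""
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm label {arm!r}")
    sub = df[df["arm"] == arm]
    return (
        sub.groupby("day", as_index=False)["volume_mm3"]
        .mean()
        .sort_values("day")
        .reset_index(drop=True)
    )


def read_pk_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PK_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"PK frame missing columns {missing}")
    return df


def write_fit_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
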