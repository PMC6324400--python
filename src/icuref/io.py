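"""Readers/writers for the stay and event tables.

The canonical interchange format is CSV with ISO-8601 timestamps, matching
what the synthetic generator writes; parquet is supported for both reading
and writing when a path ends in ``.parquet``.  ``column_map`` lets real
database extracts with different column names (e.g. upper-case MIMIC-style
headers) be remapped onto the package schema.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import InputDataError

__all__ = ["read_stays", "read_events", "write_table"]

STAY_COLUMNS = ["subject_id", "stay_id", "intime", "outtime", "age_years", "icu_death"]
EVENT_COLUMNS = ["subject_id", "stay_id", "test_id", "charttime", "value"]


def _read(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputDataError(f"input file not found: {path}")
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def _remap(df: pd.DataFrame, column_map) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return df


def read_stays(path, column_map=None) -> pd.DataFrame:
    """Read a stay table; timestamps parsed, ``icu_death`` coerced to bool."""
    df = _remap(_read(path), column_map)
    missing = [c for c in STAY_COLUMNS if c not in df.columns]
    if missing:
        raise InputDataError(f"stay table {path} missing column(s) {missing}")
    df["intime"] = pd.to_datetime(df["intime"])
    df["outtime"] = pd.to_datetime(df["outtime"])
    df["icu_death"] = df["icu_death"].astype(bool)
    df["subject_id"] = df["subject_id"].astype(str)
    df["stay_id"] = df["stay_id"].astype(str)
    return df


def read_events(path, column_map=None) -> pd.DataFrame:
    """Read a lab-event table; ``stay_id`` may be absent or partially null
    (events are then matched by subject and time window downstream)."""
    df = _remap(_read(path), column_map)
    required = [c for c in EVENT_COLUMNS if c != "stay_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputDataError(f"event table {path} missing column(s) {missing}")
    df["charttime"] = pd.to_datetime(df["charttime"])
    df["subject_id"] = df["subject_id"].astype(str)
    if "stay_id" in df.columns:
        df["stay_id"] = df["stay_id"].astype("string").astype(object)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write CSV (RFC 4180, ISO-8601 timestamps) or parquet by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False, lineterminator="\n")
    return path
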