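"""CSV schemas and readers/writers for the pipeline's tabular interfaces.

All files are plain CSV with ISO-8601 timestamps and empty fields for
missing values.  Readers validate required columns and report the offending
file and columns on schema violations.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMAS = {
    "participants": ["id", "group", "condition", "site", "age", "sex", "pss",
                     "rating_stress", "rating_unpleasant", "rating_difficulty"],
    "mrs_scans": ["id", "session", "glu_cr", "glx_cr", "cho_cr", "snr",
                  "fwhm", "crlb_glu"],
    "cortisol": ["id", "timepoint", "nmol_per_l"],
    "vams": ["id", "timepoint", "item", "score", "positive_pole"],
    "ema_surveys": ["id", "date", "schedule_index", "sent_at", "started_at",
                    "completed_at", "enthusiastic", "cheerful", "relaxed",
                    "irritable", "anxious", "sad", "expectation", "happened",
                    "outcome"],
}


class SchemaError(ValueError):
    pass


def _check(df: pd.DataFrame, name: str, path) -> pd.DataFrame:
    missing = [c for c in SCHEMAS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_table(name: str, directory) -> pd.DataFrame:
    path = Path(directory) / f"{name}.csv"
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    _check(df, name, path)
    if name == "ema_surveys":
        for col in ("sent_at", "started_at", "completed_at", "date"):
            df[col] = df[col].fillna("").astype(str)
        df["happened"] = df["happened"].map(
            lambda v: str(v).strip().lower() in ("true", "yes", "1", "1.0"))
    return df


def write_tables(tables: dict, directory) -> dict:
    """Write each table as <name>.csv; returns name -> path.

    Tables must carry at least their schema columns (extra columns, e.g. the
    generator's provenance labels, are preserved).  Empty tables produce
    header-only files that round-trip through the readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        if name in SCHEMAS:
            if df.empty and not len(df.columns):
                df = pd.DataFrame(columns=SCHEMAS[name])
            _check(df, name, f"<{name}>")
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_study(directory) -> dict:
    """Read the full fixture directory (EMA file optional)."""
    out = {}
    for name in ("participants", "mrs_scans", "cortisol", "vams"):
        out[name] = read_table(name, directory)
    ema_path = Path(directory) / "ema_surveys.csv"
    if ema_path.exists():
        out["ema_surveys"] = read_table("ema_surveys", directory)
    return out
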