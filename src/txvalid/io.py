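"""Delimited-text input/output.

All tables are plain CSV with a header row and ISO-8601 dates.  Dates are
parsed leniently: an unparseable date becomes missing (NaT) and is rejected
by the cleaning cascade rather than raising at read time.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

REFERENCE_COLUMNS = [
    "patient_key", "transplant_date", "organ", "birth_date", "sex",
    "resident", "death_date", "center",
]
SOURCE_COLUMNS = ["record_id", "source", "patient_key", "event_date", "organ"]


def _parse_dates(df: pd.DataFrame, columns) -> pd.DataFrame:
    for c in columns:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c], format="ISO8601", errors="coerce")
    return df


def read_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_key": str}, keep_default_na=True)
    missing = [c for c in REFERENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reference file {path} lacks columns {missing}")
    df["patient_key"] = df["patient_key"].fillna("")
    if df["resident"].dtype == object:
        df["resident"] = df["resident"].astype(str).str.lower().isin(["true", "1", "yes"])
    return _parse_dates(df, ["transplant_date", "birth_date", "death_date"])


def read_sources(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_key": str}, keep_default_na=True)
    required = [c for c in SOURCE_COLUMNS if c != "record_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"source file {path} lacks columns {missing}")
    if "record_id" not in df.columns:
        df.insert(0, "record_id", [f"R{i + 1:06d}" for i in range(len(df))])
    df["patient_key"] = df["patient_key"].fillna("")
    return _parse_dates(df, ["event_date"])


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[c]):
            out[c] = out[c].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return path


def write_simulation(outdir, events, patients, sources, ground_truth) -> dict[str, Path]:
    """Write the generator's outputs (reference/patients/sources/ground_truth)."""
    outdir = Path(outdir)
    return {
        "reference": _write(events, outdir / "reference.csv"),
        "patients": _write(patients, outdir / "patients.csv"),
        "sources": _write(sources, outdir / "sources.csv"),
        "ground_truth": _write(ground_truth, outdir / "ground_truth.csv"),
    }


def write_table(df: pd.DataFrame, path) -> Path:
    return _write(df, Path(path))
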