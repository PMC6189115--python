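"""CSV readers/writers for every data stream, with fixed schemas.

One file per stream: ``phenology.csv``, ``snow.csv``, ``sessions.csv``,
``captures.csv``, ``lugworms.csv``, ``histories.csv``, ``covariates.csv``,
``winter_counts.csv``, ``track.csv``.  Writers fix the column order and
keep integer columns integral so that a write -> read -> write cycle is
byte-identical.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

_SCHEMAS: dict = {
    "phenology": {
        "columns": ["year", "snowmelt_doy", "cranefly_doy", "arrival_taimyr_doy",
                    "clutch_doy", "arrival_ws_doy"],
        "int": ["year"],
    },
    "snow": {
        "columns": ["cell_id", "year", "week_start_doy", "covered"],
        "int": ["year", "week_start_doy", "covered"],
    },
    "sessions": {
        "columns": ["site_id", "year", "day", "duration_h", "count"],
        "int": ["year", "day", "count"],
    },
    "captures": {
        "columns": ["id", "year", "sex", "day", "mass_g", "capture_type"],
        "int": ["year", "day"],
    },
    "lugworms": {
        "columns": ["year", "density"],
        "int": ["year"],
    },
    "winter_counts": {
        "columns": ["site_id", "year", "count"],
        "int": ["year", "count"],
    },
    "covariates": {
        "columns": ["year", "rt", "alpha_female", "alpha_male"],
        "int": ["year"],
    },
    "track": {
        "columns": ["id", "timestamp", "lon", "lat"],
        "int": [],
    },
}


def write_stream(df: pd.DataFrame, stream: str, path) -> None:
    """Write one stream to CSV with its fixed schema."""
    path = Path(path)
    if stream == "histories":
        cols = ["id", "sex", "first_year"] + [c for c in df.columns
                                              if str(c).startswith("y")]
        df[cols].to_csv(path, index=False)
        return
    if stream not in _SCHEMAS:
        raise KeyError(f"unknown stream {stream!r}")
    schema = _SCHEMAS[stream]
    out = df[schema["columns"]].copy()
    for c in schema["int"]:
        out[c] = out[c].astype("Int64")
    out.to_csv(path, index=False)


def read_stream(stream: str, path) -> pd.DataFrame:
    """Read one stream back with its schema's dtypes."""
    path = Path(path)
    if stream == "histories":
        df = pd.read_csv(path)
        ycols = [c for c in df.columns if str(c).startswith("y")]
        df[ycols] = df[ycols].astype(int)
        return df
    if stream not in _SCHEMAS:
        raise KeyError(f"unknown stream {stream!r}")
    schema = _SCHEMAS[stream]
    df = pd.read_csv(path, float_precision="round_trip")
    for c in schema["int"]:
        df[c] = df[c].astype("Int64")
    if stream == "track":
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df[schema["columns"]]


def write_all(streams: dict, out_dir) -> None:
    """Write every generated stream into a directory (one CSV each)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for stream, df in streams.items():
        if stream == "annual_truth":
            df.to_csv(out_dir / "annual_truth.csv", index=False)
            continue
        write_stream(df, stream, out_dir / f"{stream}.csv")
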