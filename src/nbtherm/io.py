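"""Delimited-text dialect shared by all readers and writers.

Files are plain CSV with a block of ``# key: value`` header lines carrying
metadata (units, scan rate, denaturant molarity, ...), e.g.::

    # temperature_unit: C
    # scan_rate: 2.0
    # scan_kind: upscan
    temperature,cp
    20.00,0.1234
    ...

Numeric payloads are written with ``%.17g`` so that a write/read round trip
is bit-identical at float64 resolution.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


class FormatError(ValueError):
    """Raised when a tabular input file violates the expected dialect."""


def read_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a CSV with ``# key: value`` header lines.

    Returns the data frame and the metadata dict (values as strings).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise FormatError(f"{path}: could not parse table ({exc})") from exc
    return df, meta


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a CSV with ``# key: value`` header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def coerce_numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    """Coerce columns to float, naming the first offending row on failure."""
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"{path}: non-numeric value {out[col][row]!r} in column "
                f"{col!r} at data row {row}")
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise FormatError(f"{path}: missing value in column {col!r} at data row {row}")
        out[col] = converted.astype(float)
    return out
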