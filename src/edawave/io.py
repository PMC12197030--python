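"""CSV/JSON readers and writers for the package's artifacts.

All time series travel as UTF-8 comma-separated files with a ``time_s``
column plus value columns from a registered schema, written at full float
precision so a write/read round-trip is lossless.  Reports are JSON; every
CLI output directory also gets a provenance record (config hash, seed,
package version).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "TimeseriesError",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_json_report",
    "provenance",
]

#: registered header schemas: name -> required columns (time first)
SCHEMAS: dict[str, list[str]] = {
    "waveform": ["time_s", "volts"],
    "recording": ["time_s", "counts"],
    "truth": ["time_s", "g_true_uS"],
    "admittance": ["time_s", "g_uS", "b_uS", "phase_deg", "y_uS"],
    "conductance": ["time_s", "g_uS"],
    "components": ["time_s", "g_uS", "scl_uS", "scr_uS"],
}


class TimeseriesError(ValueError):
    """Malformed or unreadable time-series file."""


def write_timeseries_csv(path: str | Path, df: pd.DataFrame, schema: str | None = None) -> Path:
    """Write a time-series DataFrame at full float precision."""
    path = Path(path)
    if schema is not None:
        cols = SCHEMAS[schema]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise TimeseriesError(f"{path}: missing columns for schema {schema!r}: {missing}")
        df = df[cols]
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries_csv(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read and validate a time-series CSV; NaNs and malformed rows are fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise TimeseriesError(f"{path}: empty input file")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise TimeseriesError(f"{path}: empty input file") from exc
    except pd.errors.ParserError as exc:
        raise TimeseriesError(f"{path}: malformed CSV: {exc}") from exc
    if df.empty:
        raise TimeseriesError(f"{path}: no data rows")
    if schema is not None:
        cols = SCHEMAS[schema]
        if list(df.columns[: len(cols)]) != cols:
            raise TimeseriesError(
                f"{path}: header {list(df.columns)} does not match schema {schema!r} ({cols})"
            )
    bad = df.isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        col = bad.columns[bad.loc[row].to_numpy().argmax()]
        # +2: header line plus 1-based numbering
        raise TimeseriesError(f"{path}: NaN/missing value at line {row + 2}, column {col!r}")
    non_num = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_num:
        raise TimeseriesError(f"{path}: non-numeric columns {non_num}")
    return df


def write_json_report(path: str | Path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def provenance(config_text: str, seed: int | None) -> dict:
    """Provenance record attached to every CLI output."""
    from . import __version__

    return {
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
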