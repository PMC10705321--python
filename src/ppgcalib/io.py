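"""CSV / JSON formats for traces, sweeps, calibrations, and tables.

All formats are plain text.  The trace format is the contract with any
real capture app: one row per frame with the exact header
``frame_index,timestamp_ms,red,green,blue`` and 8-bit integer pixel
values.  Malformed files are rejected with the offending line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .errors import FormatError
from .pipeline import PixelTrace

TRACE_COLUMNS = ("frame_index", "timestamp_ms", "red", "green", "blue")
SWEEP_COLUMNS = ("brightness", "red", "green", "blue")


def write_trace(trace: PixelTrace, path: str | Path) -> None:
    """Write a pixel trace as CSV with the canonical header."""
    df = pd.DataFrame(
        {
            "frame_index": np.arange(trace.n_frames),
            "timestamp_ms": trace.timestamps_ms,
            "red": trace.channels.get("red", np.zeros(trace.n_frames, dtype=int)),
            "green": trace.channels.get("green", np.zeros(trace.n_frames, dtype=int)),
            "blue": trace.channels.get("blue", np.zeros(trace.n_frames, dtype=int)),
        }
    )
    df.to_csv(path, index=False)


def read_trace(path: str | Path) -> PixelTrace:
    """Read and validate a trace CSV; lossless integer round-trip.

    Raises
    ------
    FormatError
        On a wrong header, non-numeric or out-of-range pixel values, or
        non-monotone timestamps — with the 1-based line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    if tuple(header.split(",")) != TRACE_COLUMNS:
        raise FormatError(
            f"{path}: line 1: header must be exactly {','.join(TRACE_COLUMNS)!r}"
        )
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas reports its own line numbers
        raise FormatError(f"{path}: unparseable CSV: {exc}") from exc
    for col in ("red", "green", "blue"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values)) | (values < 0) | (values > 255)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(
                f"{path}: line {line}: column {col!r} must be an integer in [0, 255]"
            )
    ts = pd.to_numeric(df["timestamp_ms"], errors="coerce")
    if ts.isna().any():
        line = int(ts.isna().idxmax()) + 2
        raise FormatError(f"{path}: line {line}: non-numeric timestamp")
    non_mono = np.flatnonzero(np.diff(ts.to_numpy()) <= 0)
    if non_mono.size:
        line = int(non_mono[0]) + 3
        raise FormatError(f"{path}: line {line}: timestamps must be strictly increasing")
    return PixelTrace(
        timestamps_ms=ts.to_numpy(float),
        channels={c: df[c].to_numpy(np.int64) for c in ("red", "green", "blue")},
    )


def write_sweep(
    brightness: Sequence[float], pixels: Mapping[str, Sequence[int]], path: str | Path
) -> None:
    """Write a calibration sweep recording (commanded brightness vs pixels)."""
    n = len(brightness)
    df = pd.DataFrame(
        {
            "brightness": np.asarray(brightness, float),
            "red": np.asarray(pixels.get("red", np.zeros(n, int))),
            "green": np.asarray(pixels.get("green", np.zeros(n, int))),
            "blue": np.asarray(pixels.get("blue", np.zeros(n, int))),
        }
    )
    df.to_csv(path, index=False)


def read_sweep(path: str | Path) -> Tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a sweep CSV back as (brightness, per-channel pixel arrays)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    if tuple(header.split(",")) != SWEEP_COLUMNS:
        raise FormatError(
            f"{path}: line 1: header must be exactly {','.join(SWEEP_COLUMNS)!r}"
        )
    df = pd.read_csv(path)
    brightness = pd.to_numeric(df["brightness"], errors="coerce")
    if brightness.isna().any():
        line = int(brightness.isna().idxmax()) + 2
        raise FormatError(f"{path}: line {line}: non-numeric brightness")
    return brightness.to_numpy(float), {
        c: df[c].to_numpy(float) for c in ("red", "green", "blue")
    }


def write_calibration(result: CalibrationResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2) + "\n")


def read_calibration(path: str | Path) -> CalibrationResult:
    try:
        return CalibrationResult.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, TypeError) as exc:
        raise FormatError(f"{path}: not a valid calibration record: {exc}") from exc


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
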