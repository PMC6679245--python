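"""Plain-text RR-interval input/output.

Two layouts are supported:

``durations_text``
    one RR-interval per line; timestamps are reconstructed by cumulative sum
    anchored at 0 (the anchor time of the original recording is not stored).
``timestamps_csv``
    CSV with columns ``beat_index,timestamp_s`` (or ``timestamp_ms``).

Units may be seconds or milliseconds.  Malformed lines are reported with
their line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .series import BeatSeries

__all__ = ["read_rr", "write_rr"]

LAYOUTS = ("durations_text", "timestamps_csv")
UNITS = ("s", "ms")


def _check_args(layout: str, units: str):
    if layout not in LAYOUTS:
        raise InvalidParameterError(f"layout must be one of {LAYOUTS}; got {layout!r}")
    if units not in UNITS:
        raise InvalidParameterError(f"units must be one of {UNITS}; got {units!r}")


def read_rr(path, layout: str = "durations_text", units: str = "s") -> BeatSeries:
    """Read a beat series from a plain-text file.

    Durations are converted to timestamps by cumulative sum anchored at 0;
    milliseconds are converted to seconds.
    """
    _check_args(layout, units)
    path = Path(path)
    scale = 1.0 if units == "s" else 1e-3

    if layout == "durations_text":
        durations = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                try:
                    v = float(s)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric value {s!r}") from None
                if v <= 0:
                    raise FormatError(f"{path}:{lineno}: non-positive duration {v}")
                durations.append(v * scale)
        ts = np.concatenate([[0.0], np.cumsum(durations)]) if durations else np.array([0.0])
        if not durations:
            ts = np.array([])
        return BeatSeries(ts)

    # timestamps_csv
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from None
    col = "timestamp_s" if units == "s" else "timestamp_ms"
    if col not in df.columns:
        raise FormatError(f"{path}: missing required column {col!r}")
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna()]
    if len(bad):
        raise FormatError(f"{path}: non-numeric timestamp at data row {bad[0] + 1}")
    ts = vals.to_numpy(dtype=float) * scale
    if len(ts) >= 2:
        nonmono = np.flatnonzero(np.diff(ts) <= 0)
        if len(nonmono):
            raise FormatError(
                f"{path}: timestamps not strictly increasing at data row {nonmono[0] + 2}")
    return BeatSeries(ts)


def write_rr(beats: BeatSeries, path, layout: str = "durations_text",
             units: str = "s") -> Path:
    """Write a beat series; read_rr(write_rr(x)) round-trips to formatting precision.

    The durations layout drops the anchor time: a series read back from it
    always starts at timestamp 0.
    """
    _check_args(layout, units)
    path = Path(path)
    scale = 1.0 if units == "s" else 1e3

    if layout == "durations_text":
        with open(path, "w") as fh:
            for d in beats.durations:
                fh.write(f"{d * scale:.9f}\n")
        return path

    col = "timestamp_s" if units == "s" else "timestamp_ms"
    df = pd.DataFrame({
        "beat_index": np.arange(beats.n_beats, dtype=int),
        col: beats.timestamps * scale,
    })
    df.to_csv(path, index=False, float_format="%.9f")
    return path
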