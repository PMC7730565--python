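"""Signal file I/O, configuration and quality-report serialization.

Signals travel as two-column CSV files (``time,value``, time in seconds,
one row per sample) with the sampling rate, units and kind supplied
out-of-band (CLI flags or config).  The reader validates grid uniformity to
within 1e-6 s jitter and re-grids by interpolation (with a warning) when the
time column has gaps.  Reports are JSON: every aggregate they contain is
reproducible from the per-segment arrays in the same report, and all
pipeline parameters actually used are echoed verbatim.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import MalformedInputError
from .signals import SessionMarkers, UniformSignal

REPORT_SCHEMA_VERSION = 1


def read_signal_csv(path, fs: float = None, units: str = "a.u.",
                    kind: str = "other") -> UniformSignal:
    """Read a ``time,value`` CSV into a :class:`UniformSignal`.

    When ``fs`` is omitted it is inferred from the median time step.  A
    non-uniform grid (jitter beyond 1e-6 s) is re-gridded by linear
    interpolation with a warning recorded in the signal's metadata.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise MalformedInputError(f"{path}: need two columns (time, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise MalformedInputError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise MalformedInputError(f"{path}: time column must be strictly increasing")
    step = float(np.median(dt))
    if fs is None:
        fs = 1.0 / step
    meta = {}
    if np.max(np.abs(dt - 1.0 / fs)) > 1e-6:
        msg = f"{path}: non-uniform time grid; re-gridded at {fs} Hz"
        warnings.warn(msg)
        meta["warnings"] = [msg]
        n = int(round((t[-1] - t[0]) * fs)) + 1
        tg = t[0] + np.arange(n) / fs
        v = np.interp(tg, t, v)
    return UniformSignal(v, fs=float(fs), t0=float(t[0]), units=units,
                         kind=kind, meta=meta)


def write_signal_csv(path, signal: UniformSignal) -> None:
    pd.DataFrame({"time": signal.times, "value": signal.values}).to_csv(
        path, index=False, float_format="%.9g")


def read_markers_csv(path) -> SessionMarkers:
    """Read a ``label,time`` CSV into :class:`SessionMarkers`."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise MalformedInputError(f"{path}: need two columns (label, time)")
    return SessionMarkers(tuple(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))


def read_beats_csv(path) -> np.ndarray:
    """Read a single-column ``time`` CSV of beat times (seconds)."""
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(dtype=float)


def write_beats_csv(path, beat_times) -> None:
    pd.DataFrame({"time": np.asarray(beat_times, float)}).to_csv(
        path, index=False, float_format="%.9g")


def read_ibi_csv(path):
    """Read an IBI CSV with columns ``time,ibi,valid``."""
    from .ibi import IBISeries

    df = pd.read_csv(path)
    for col in ("time", "ibi", "valid"):
        if col not in df.columns:
            raise MalformedInputError(f"{path}: missing column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    ibi = df["ibi"].to_numpy(dtype=float)[1:]  # first beat terminates no IBI
    valid = df["valid"].to_numpy(dtype=bool)
    return IBISeries(t, ibi, valid)


def write_ibi_csv(path, ibi) -> None:
    pd.DataFrame({
        "time": ibi.beat_times,
        "ibi": np.concatenate(([np.nan], ibi.ibi_values)),
        "valid": ibi.valid.astype(int),
    }).to_csv(path, index=False, float_format="%.9g")


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def build_report(input_descriptor: dict, parameters: dict, results: dict,
                 warnings_list=()) -> dict:
    """Assemble a versioned quality report (JSON-serializable dict)."""
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": __version__,
        "input": _to_jsonable(input_descriptor),
        "parameters": _to_jsonable(parameters),
        "results": _to_jsonable(results),
        "warnings": list(warnings_list),
    }


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
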