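"""Uniform time-series container and preprocessing primitives.

Every downstream stage (cardiac SQIs, beat detection, EDA metrics) operates on
:class:`UniformSignal`: a uniformly sampled single-channel series with a
sampling rate, a start time and unit/kind labels.  Sample ``i`` lives at time
``t0 + i / fs`` (0-based).  Segmentation uses half-open windows and drops a
trailing partial window, so aggregated per-window statistics are means over
complete windows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import DegenerateSignalError, InvalidArgumentError

SIGNAL_KINDS = ("ecg", "bvp", "eda", "acc", "other")


@dataclass(frozen=True)
class UniformSignal:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values; length >= 1, no gaps (uniform grid by construction).
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Unit label (mV, uS, g, a.u., z-units, ...).
    kind : str
        One of ``ecg, bvp, eda, acc, other``.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    units: str = "a.u."
    kind: str = "other"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidArgumentError("values must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise InvalidArgumentError(f"fs must be > 0, got {self.fs}")
        if self.kind not in SIGNAL_KINDS:
            raise InvalidArgumentError(f"kind must be one of {SIGNAL_KINDS}")
        object.__setattr__(self, "values", vals)

    # -- basic geometry -------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Signal extent in seconds (n / fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def time_to_index(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the extent)."""
        idx = int(round((t - self.t0) * self.fs))
        return min(max(idx, 0), len(self) - 1)

    def with_values(self, values: np.ndarray, **changes) -> "UniformSignal":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass(frozen=True)
class Segment(UniformSignal):
    """A windowed slice of a parent signal (half-open index interval)."""

    start_index: int = 0
    end_index: int = 0
    width_s: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        if self.end_index <= self.start_index:
            raise InvalidArgumentError("segment end must exceed start")


@dataclass(frozen=True)
class SessionMarkers:
    """Ordered (label, time_s) event markers used to split sessions.

    Times must be non-decreasing; ties are allowed so contiguous sessions
    can share a boundary (one phase's end marker coincides with the next
    phase's start marker).
    """

    events: tuple

    def __post_init__(self):
        events = tuple((str(lbl), float(t)) for lbl, t in self.events)
        times = [t for _, t in events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("marker times must be non-decreasing")
        object.__setattr__(self, "events", events)

    def intervals(self) -> dict:
        """Pair ``X_start`` / ``X_end`` markers into labelled [start, end) intervals.

        Markers not following the ``_start``/``_end`` convention are paired
        consecutively and labelled by the first marker's label.
        """
        out: dict[str, tuple[float, float]] = {}
        open_: dict[str, float] = {}
        pending: list[tuple[str, float]] = []
        for label, t in self.events:
            if label.endswith("_start"):
                open_[label[: -len("_start")]] = t
            elif label.endswith("_end"):
                name = label[: -len("_end")]
                if name not in open_:
                    raise InvalidArgumentError(f"'{label}' has no matching start")
                out[name] = (open_.pop(name), t)
            else:
                pending.append((label, t))
        if open_:
            raise InvalidArgumentError(f"unclosed markers: {sorted(open_)}")
        for (l1, t1), (_, t2) in zip(pending[::2], pending[1::2]):
            out[l1] = (t1, t2)
        return out


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def resample(signal: UniformSignal, target_fs: float) -> UniformSignal:
    """Resample to ``target_fs`` preserving duration to within one sample.

    Uses polyphase resampling (with the built-in anti-alias filter) when the
    rate ratio is rational with small terms, otherwise linear interpolation
    after an explicit anti-alias low-pass for downsampling.  The method used
    is recorded in the output's ``meta['resample_method']``.
    """
    if not target_fs > 0:
        raise InvalidArgumentError(f"target_fs must be > 0, got {target_fs}")
    if np.isclose(target_fs, signal.fs, rtol=1e-12):
        return replace(signal, meta={**signal.meta, "resample_method": "identity"})

    frac = Fraction(target_fs / signal.fs).limit_denominator(1000)
    n_out = int(round(len(signal) * target_fs / signal.fs))
    if abs(float(frac) - target_fs / signal.fs) < 1e-12:
        out = sps.resample_poly(signal.values, frac.numerator, frac.denominator)
        out = out[:n_out] if out.size >= n_out else np.pad(out, (0, n_out - out.size), mode="edge")
        method = "polyphase"
    else:
        x = signal.values
        if target_fs < signal.fs:  # anti-alias before decimation
            sos = sps.butter(8, 0.45 * target_fs / (signal.fs / 2), output="sos")
            x = sps.sosfiltfilt(sos, x)
        t_new = np.arange(n_out) / target_fs
        out = np.interp(t_new, np.arange(len(signal)) / signal.fs, x)
        method = "linear-interp"
    return signal.with_values(out, fs=float(target_fs),
                              meta={**signal.meta, "resample_method": method})


def filter_band(signal: UniformSignal, band_type: str, cutoffs, order: int = 4) -> UniformSignal:
    """Zero-phase Butterworth filter (applied forward-backward).

    ``band_type`` is ``low``, ``high`` or ``band``; ``cutoffs`` is one cutoff
    (Hz) for low/high, a (low, high) pair for band.  Zero-phase filtering
    preserves beat timing.  Cutoffs must lie strictly inside (0, fs/2).
    """
    nyq = signal.fs / 2
    c = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if np.any(c <= 0) or np.any(c >= nyq):
        raise InvalidArgumentError(
            f"cutoffs {cutoffs} must lie strictly inside (0, {nyq}) Hz")
    if band_type == "band":
        if c.size != 2 or c[0] >= c[1]:
            raise InvalidArgumentError("band filter needs cutoffs (low, high), low < high")
        sos = sps.butter(order, c / nyq, btype="bandpass", output="sos")
    elif band_type in ("low", "high"):
        if c.size != 1:
            raise InvalidArgumentError(f"{band_type}-pass filter needs one cutoff")
        sos = sps.butter(order, c[0] / nyq, btype=band_type, output="sos")
    else:
        raise InvalidArgumentError(f"band_type must be low|high|band, got {band_type!r}")
    return signal.with_values(sps.sosfiltfilt(sos, signal.values))


def standardize(signal: UniformSignal) -> UniformSignal:
    """Z-score the whole signal; output mean 0, sd 1, units ``z-units``."""
    sd = float(np.std(signal.values))
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSignalError("cannot standardize a constant signal")
    out = (signal.values - np.mean(signal.values)) / sd
    return signal.with_values(out, units="z-units")


def segment(signal: UniformSignal, width_s: float, overlap_s: float = 0.0) -> list:
    """Split into windows of ``width_s`` seconds with ``overlap_s`` overlap.

    Windows start every ``width_s - overlap_s`` seconds; a trailing portion
    shorter than a full window is dropped.  Returns a (possibly empty) list of
    :class:`Segment`.
    """
    if not (0 <= overlap_s < width_s):
        raise InvalidArgumentError("require 0 <= overlap_s < width_s")
    win = int(round(width_s * signal.fs))
    step = int(round((width_s - overlap_s) * signal.fs))
    if win < 1 or step < 1:
        raise InvalidArgumentError("window/step shorter than one sample")
    n = len(signal)
    if n < win:
        warnings.warn("signal shorter than one window; no segments produced")
        return []
    segments = []
    for start in range(0, n - win + 1, step):
        segments.append(Segment(
            values=signal.values[start:start + win], fs=signal.fs,
            t0=signal.t0 + start / signal.fs, units=signal.units,
            kind=signal.kind, start_index=start, end_index=start + win,
            width_s=width_s))
    return segments


def acceleration_module(x: UniformSignal, y: UniformSignal, z: UniformSignal) -> UniformSignal:
    """Per-sample Euclidean norm of a 3-axis acceleration recording (units g)."""
    if not (len(x) == len(y) == len(z)) or not np.isclose(x.fs, y.fs) or not np.isclose(x.fs, z.fs):
        raise InvalidArgumentError("acceleration axes must share length and sampling rate")
    norm = np.sqrt(x.values ** 2 + y.values ** 2 + z.values ** 2)
    return x.with_values(norm, units="g", kind="acc")


def split_sessions(signal: UniformSignal, markers: SessionMarkers) -> dict:
    """Slice the signal into labelled [start, end) sessions.

    Marker times are rounded to the nearest sample; all markers must fall
    within the signal extent.
    """
    out = {}
    t_end = signal.t0 + len(signal) / signal.fs
    for label, (a, b) in markers.intervals().items():
        if a < signal.t0 - 0.5 / signal.fs or b > t_end + 0.5 / signal.fs:
            raise InvalidArgumentError(
                f"markers for '{label}' [{a}, {b}) outside signal extent")
        i0 = int(round((a - signal.t0) * signal.fs))
        i1 = int(round((b - signal.t0) * signal.fs))
        i0, i1 = max(i0, 0), min(i1, len(signal))
        out[label] = signal.with_values(signal.values[i0:i1],
                                        t0=signal.t0 + i0 / signal.fs)
    return out
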