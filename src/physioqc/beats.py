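"""Heartbeat detectors.

Two detectors are provided:

* :func:`abd_detect` — adaptive beat detection for ECG.  The signal's local
  range (per-window max - min, 1 s windows with 0.5 s overlap) serves as an
  adaptive amplitude scale; a local maximum is accepted as an R peak when it
  is followed, within a short lookahead, by a local minimum at least
  0.7 x local range below it.  Because the threshold is relative to the local
  range, detections are invariant to amplitude scaling and track slow gain
  drifts.

* :func:`derivative_bvp_detect` — derivative-based pulse detection for BVP.
  One fiducial per pulse is placed at the maximum of the first derivative
  (the steepest systolic upslope), gated by an adaptive threshold on the
  positive derivative (0.5 x its rolling 75th percentile over 10 s).

Both enforce a refractory period (default 0.25 s, a 240 bpm physiological
ceiling) so one QRS complex or pulse cannot yield two beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidArgumentError
from .signals import UniformSignal, filter_band

REFRACTORY_S = 0.25
ABD_RANGE_FRACTION = 0.7
ABD_LOOKAHEAD_S = 0.35  # QRS downstroke scale


@dataclass(frozen=True)
class BeatSeries:
    """Detected beat times (strictly increasing, seconds)."""

    beat_times: np.ndarray
    source_kind: str = "ecg"
    fs_of_source: float = float("nan")

    def __post_init__(self):
        t = np.asarray(self.beat_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", t)

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass(frozen=True)
class LocalRangeEnvelope:
    """Windowed range (max - min) of a signal; step-wise evaluable in time."""

    centers: np.ndarray
    ranges: np.ndarray
    width_s: float
    overlap_s: float

    def at(self, t) -> np.ndarray:
        """Range of the window whose centre is nearest to time(s) ``t``."""
        idx = np.searchsorted(self.centers, np.atleast_1d(t))
        idx = np.clip(idx, 0, len(self.centers) - 1)
        prev = np.clip(idx - 1, 0, len(self.centers) - 1)
        use_prev = np.abs(np.atleast_1d(t) - self.centers[prev]) <= np.abs(
            np.atleast_1d(t) - self.centers[idx])
        out = np.where(use_prev, self.ranges[prev], self.ranges[idx])
        return out if np.ndim(t) else float(out[0])


def local_range(signal: UniformSignal, width_s: float = 1.0,
                overlap_s: float = 0.5) -> LocalRangeEnvelope:
    """Per-window max - min envelope (1 s windows, 0.5 s overlap by default)."""
    win = int(round(width_s * signal.fs))
    step = int(round((width_s - overlap_s) * signal.fs))
    n = len(signal)
    if n < win:
        warnings.warn("signal shorter than one local-range window")
        return LocalRangeEnvelope(np.asarray([signal.t0 + n / (2 * signal.fs)]),
                                  np.asarray([float(np.ptp(signal.values))]),
                                  width_s, overlap_s)
    starts = np.arange(0, n - win + 1, step)
    # sliding window via stride tricks would hold the whole matrix; windows
    # here are few (2 per second) so a loop is simpler and cheap
    ranges = np.asarray([np.ptp(signal.values[s:s + win]) for s in starts], dtype=float)
    centers = signal.t0 + (starts + win / 2) / signal.fs
    return LocalRangeEnvelope(centers, ranges, width_s, overlap_s)


def _refractory_filter(times: np.ndarray, refractory_s: float) -> np.ndarray:
    keep = []
    last = -np.inf
    for t in times:
        if t - last >= refractory_s:
            keep.append(t)
            last = t
    return np.asarray(keep)


def abd_detect(ecg: UniformSignal, range_fraction: float = ABD_RANGE_FRACTION,
               lookahead_s: float = ABD_LOOKAHEAD_S,
               refractory_s: float = REFRACTORY_S) -> BeatSeries:
    """Adaptive beat detection on an ECG signal.

    Scans local maxima in order; a maximum is a beat when the drop to the
    next local minimum (within ``lookahead_s``) exceeds
    ``range_fraction`` x the local range at that time.  Ties between
    equal-height maxima resolve to the earliest; a refractory period
    suppresses double detections.
    """
    x = ecg.values
    if np.ptp(x) == 0:
        return BeatSeries(np.asarray([]), "ecg", ecg.fs)
    env = local_range(ecg)
    maxima, _ = sps.find_peaks(x)
    minima, _ = sps.find_peaks(-x)
    look = max(1, int(round(lookahead_s * ecg.fs)))
    accepted = []
    for m in maxima:
        j = np.searchsorted(minima, m)
        if j >= minima.size:
            continue
        nxt = minima[j]
        if nxt - m > look:
            continue
        t = ecg.t0 + m / ecg.fs
        if x[m] - x[nxt] > range_fraction * env.at(t):
            accepted.append(t)
    return BeatSeries(_refractory_filter(np.asarray(accepted), refractory_s),
                      "ecg", ecg.fs)


def derivative_bvp_detect(bvp: UniformSignal, band=(0.5, 16.0),
                          threshold_fraction: float = 0.5,
                          percentile: float = 90.0,
                          percentile_window_s: float = 10.0,
                          refractory_s: float = REFRACTORY_S) -> BeatSeries:
    """Derivative-based pulse detection on a BVP signal.

    Band-pass the signal, take the first difference, threshold it at
    ``threshold_fraction`` x the rolling ``percentile``-th percentile of the
    strictly positive derivative samples (window ``percentile_window_s``),
    and place one beat per supra-threshold run at the derivative maximum —
    the steepest point of the systolic upslope.  The percentile is taken
    over positive samples only: the derivative is non-positive for most of
    the pulse cycle, so a percentile over all samples would sit near zero
    and admit the dicrotic-notch upslope as a second beat.
    """
    if np.ptp(bvp.values) == 0:
        return BeatSeries(np.asarray([]), "bvp", bvp.fs)
    hi = min(band[1], 0.45 * bvp.fs)
    filt = filter_band(bvp, "band", (band[0], hi))
    deriv = np.diff(filt.values) * bvp.fs
    pos = pd.Series(np.where(deriv > 0, deriv, np.nan))
    win = max(3, int(round(percentile_window_s * bvp.fs)))
    roll = (pos.rolling(win, center=True, min_periods=1)
            .quantile(percentile / 100.0).to_numpy())
    thr = threshold_fraction * np.nan_to_num(roll, nan=np.inf)
    above = deriv > np.maximum(thr, 1e-12)
    if not np.any(above):
        return BeatSeries(np.asarray([]), "bvp", bvp.fs)
    run_starts = []
    run_ends = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            run_starts.append(i)
            run_ends.append(j)
            i = j
        else:
            i += 1
    times = []
    for a, b in zip(run_starts, run_ends):
        k = a + int(np.argmax(deriv[a:b]))
        times.append(bvp.t0 + k / bvp.fs)
    return BeatSeries(_refractory_filter(np.asarray(times), refractory_s),
                      "bvp", bvp.fs)
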