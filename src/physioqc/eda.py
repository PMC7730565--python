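"""Electrodermal-activity quality metrics: roor, nj and alpha.

Three metrics judge an EDA (skin conductance) recording:

* ``roor`` — ratio of out-of-range samples: fraction of samples above 60 uS
  or below 0.05 uS, the physiological range of skin conductance.  Good when
  roor <= 0.05.
* ``nj`` — normalized jump count.  The signal is detrended by subtracting
  its 0.05 Hz low-pass component; the derivative of the detrended signal
  ``sf`` is normalized by the standard deviation of ``sf`` and each maximal
  contiguous run with |dn| > 10 counts as one jump (a discontinuity
  artifact).  Normalizing by sigma makes the count invariant to device gain,
  unlike a fixed uS/s rule.  Good when nj <= 5 over a 5-minute session (at
  most one jump per minute).
* ``alpha`` — signal activity: the RMS of the detrended signal ``sf``, in
  uS.  A recording with no skin-conductance responses (or responses below
  the 0.05 uS minimal peak amplitude) gives alpha < 0.05 uS and is flagged
  bad.

Preprocessing: low-pass at 1.5 Hz and downsample to 4 Hz (clinical-grade
recordings are downsampled so metrics are comparable across devices).
Metrics are computed on non-overlapping 20 s windows; roor and alpha are
averaged across windows, nj is summed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidArgumentError
from .signals import UniformSignal, filter_band, resample, segment

ROOR_LO_US = 0.05
ROOR_HI_US = 60.0
ROOR_GOOD_MAX = 0.05
JUMP_DN_THRESHOLD = 10.0
NJ_GOOD_MAX = 5
ALPHA_GOOD_MIN_US = 0.05
EDA_FS = 4.0
EDA_LOWPASS_HZ = 1.5
TREND_CUTOFF_HZ = 0.05
WINDOW_S = 20.0


@dataclass(frozen=True)
class EDASQI:
    """Per-segment and aggregated EDA quality metrics with good/bad flags."""

    roor_per_segment: np.ndarray
    nj_per_segment: np.ndarray
    alpha_per_segment: np.ndarray
    roor: float      # mean over segments
    nj: int          # sum over segments
    alpha: float     # mean over segments, uS
    n_segments: int
    jump_times: np.ndarray  # run-start times, s
    roor_good: bool
    nj_good: bool
    alpha_good: bool
    params: dict = field(default_factory=dict, compare=False)


def preprocess_eda(signal: UniformSignal) -> UniformSignal:
    """Downsample to 4 Hz (when above) and low-pass at 1.5 Hz."""
    out = signal
    if signal.fs > EDA_FS:
        out = resample(out, EDA_FS)
    elif signal.fs < EDA_FS:
        warnings.warn(f"EDA sampled at {signal.fs} Hz < {EDA_FS} Hz; not resampled")
    return filter_band(out, "low", EDA_LOWPASS_HZ)


def detrend_eda(signal: UniformSignal, mode: str = "subtract-trend") -> UniformSignal:
    """Remove tonic level and long-term drift, yielding the fast component sf.

    The trend is the 0.05 Hz low-pass of the signal; ``sf = signal - trend``
    (equivalently a 0.05 Hz high-pass).  ``mode='lowpass'`` instead returns
    the literal 0.05 Hz low-pass output, provided for comparison only.
    """
    trend = filter_band(signal, "low", TREND_CUTOFF_HZ)
    if mode == "lowpass":
        return trend
    if mode != "subtract-trend":
        raise InvalidArgumentError("mode must be 'subtract-trend' or 'lowpass'")
    return signal.with_values(signal.values - trend.values)


def roor(values, lo: float = ROOR_LO_US, hi: float = ROOR_HI_US) -> float:
    """Fraction of samples outside the physiological range [lo, hi] uS.

    Computed on the preprocessed but *not* detrended signal — the range
    limits are absolute conductance levels.
    """
    x = np.asarray(getattr(values, "values", values), dtype=float)
    return float(np.count_nonzero((x > hi) | (x < lo)) / x.size)


def normalized_jumps(sf: UniformSignal, threshold: float = JUMP_DN_THRESHOLD):
    """Count jumps in the detrended signal sf.

    ``dn = sf' / sigma(sf)`` with the derivative as first difference x fs and
    sigma the standard deviation of sf over the whole recording.  A jump is
    one maximal contiguous run of samples with |dn| > threshold.  Returns
    ``(nj, jump_start_times)``.
    """
    x = sf.values
    sigma = float(np.std(x))
    if sigma == 0:
        warnings.warn("degenerate (constant) detrended signal; zero jumps")
        return 0, np.asarray([])
    dn = np.diff(x) * sf.fs / sigma
    above = np.abs(dn) > threshold
    if not np.any(above):
        return 0, np.asarray([])
    # run starts: sample where `above` turns on
    starts = np.flatnonzero(np.diff(np.concatenate(([False], above)).astype(int)) == 1)
    times = sf.t0 + starts / sf.fs
    return int(starts.size), times


def signal_activity(values, mean_square: bool = False) -> float:
    """alpha: RMS of the detrended signal sf, in uS.

    ``mean_square=True`` omits the radical (sensitivity analysis only; the
    0.05 uS threshold is on the RMS scale).
    """
    x = np.asarray(getattr(values, "values", values), dtype=float)
    ms = float(np.mean(x ** 2))
    return ms if mean_square else float(np.sqrt(ms))


def eda_sqi(signal: UniformSignal, detrend_mode: str = "subtract-trend") -> EDASQI:
    """Full EDA quality pipeline.

    Preprocess (4 Hz, 1.5 Hz low-pass), detrend once on the whole recording,
    cut into non-overlapping 20 s windows, compute roor (preprocessed
    values), alpha (detrended values) and jump runs (assigned to the window
    containing the run start) per window, and aggregate: mean roor, summed
    nj, mean alpha, with threshold flags.
    """
    if signal.duration < WINDOW_S:
        raise InsufficientDataError("eda_sqi", f"duration < one {WINDOW_S} s window")
    prepped = preprocess_eda(signal)
    sf = detrend_eda(prepped, mode=detrend_mode)
    nj_total, jump_times = normalized_jumps(sf)

    segs_raw = segment(prepped, WINDOW_S, 0.0)
    segs_sf = segment(sf, WINDOW_S, 0.0)
    roors = np.asarray([roor(s) for s in segs_raw])
    alphas = np.asarray([signal_activity(s) for s in segs_sf])
    njs = np.zeros(len(segs_sf), dtype=int)
    covered_end = segs_sf[-1].t0 + WINDOW_S if segs_sf else sf.t0
    for t in jump_times:
        if t < covered_end:
            idx = int((t - sf.t0) // WINDOW_S)
            njs[min(idx, len(njs) - 1)] += 1
    nj_sum = int(njs.sum())  # jumps in the trailing partial window are dropped with it

    roor_mean = float(np.mean(roors))
    alpha_mean = float(np.mean(alphas))
    return EDASQI(
        roor_per_segment=roors, nj_per_segment=njs, alpha_per_segment=alphas,
        roor=roor_mean, nj=nj_sum, alpha=alpha_mean, n_segments=len(segs_raw),
        jump_times=jump_times[jump_times < covered_end],
        roor_good=roor_mean <= ROOR_GOOD_MAX,
        nj_good=nj_sum <= NJ_GOOD_MAX,
        alpha_good=alpha_mean >= ALPHA_GOOD_MIN_US,
        params={"fs": EDA_FS, "lowpass_hz": EDA_LOWPASS_HZ,
                "trend_cutoff_hz": TREND_CUTOFF_HZ, "window_s": WINDOW_S,
                "roor_range_uS": (ROOR_LO_US, ROOR_HI_US),
                "jump_threshold": JUMP_DN_THRESHOLD,
                "detrend_mode": detrend_mode})
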