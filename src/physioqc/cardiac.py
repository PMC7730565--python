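"""Cardiac signal-quality indicators: kurtosis and spectral power ratio.

Two SQIs computed directly on the signal, without requiring beat detection:

* ``K`` — Pearson (non-excess) kurtosis.  Gaussian noise gives K ~ 3; a good
  ECG is spiky (sharp QRS complexes against a flat baseline) and gives K > 5,
  while a good BVP pulse wave is smooth and gives K < 3.5.
* ``psi`` — spectral power ratio: band power in a beat-information band F1
  divided by band power in a broad band F2 containing all main components.
  With F1 inside F2 the ratio lies in [0, 1]; values between 0.5 and 0.8 are
  expected for good cardiac signals.

The full pipeline resamples to 128 Hz, band-passes [0.5, 50] Hz, standardizes,
splits into non-overlapping 5 s windows, computes both SQIs per window and
reports their arithmetic means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .errors import DegenerateSignalError, InvalidArgumentError, UndefinedRatioError
from .signals import UniformSignal, filter_band, resample, segment, standardize

#: Beat-information / broadband frequency bands per signal kind, in Hz.
DEFAULT_BANDS = {
    "ecg": ((5.0, 14.0), (5.0, 50.0)),
    "bvp": ((1.0, 2.25), (0.0, 8.0)),
}

#: Quality thresholds: ECG kurtosis must exceed 5, BVP kurtosis stay below
#: 3.5, and for both kinds psi must lie in [0.5, 0.8].
K_THRESHOLD_ECG = 5.0
K_THRESHOLD_BVP = 3.5
PSI_RANGE = (0.5, 0.8)

PIPELINE_FS = 128.0
PIPELINE_BAND = (0.5, 50.0)
WINDOW_S = 5.0


@dataclass(frozen=True)
class SpectralBands:
    """F1 (beat information) and F2 (broadband) bands; F1 must lie inside F2."""

    F1: tuple
    F2: tuple

    def __post_init__(self):
        (f1l, f1h), (f2l, f2h) = self.F1, self.F2
        if not (f1l < f1h and f2l < f2h):
            raise InvalidArgumentError("each band needs low < high")
        if not (f2l <= f1l and f1h <= f2h):
            raise InvalidArgumentError("F1 must be contained in F2 (guarantees psi in [0,1])")


@dataclass(frozen=True)
class CardiacSQI:
    """Per-segment and aggregated cardiac quality indicators."""

    K_per_segment: np.ndarray
    psi_per_segment: np.ndarray
    K: float
    psi: float
    n_segments: int
    n_excluded: int
    kind: str
    K_good: bool
    psi_good: bool
    params: dict = field(default_factory=dict, compare=False)


def kurtosis(values, excess: bool = False) -> float:
    """Pearson kurtosis: fourth central moment over squared variance.

    ``excess=True`` subtracts 3 (Fisher convention).  Raises on a constant
    input, where the ratio is undefined.
    """
    x = np.asarray(getattr(values, "values", values), dtype=float)
    if np.std(x) == 0:
        raise DegenerateSignalError("kurtosis undefined for a constant segment")
    return float(stats.kurtosis(x, fisher=excess, bias=True))


def _welch_psd(x: np.ndarray, fs: float):
    nper = min(len(x), int(round(2 * fs)))
    return sps.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)


def band_power(freqs: np.ndarray, psd: np.ndarray, band) -> float:
    """Integrate the PSD over bins whose centre lies in half-open [low, high)."""
    low, high = band
    mask = (freqs >= low) & (freqs < high)
    if not np.any(mask):
        raise InvalidArgumentError(
            f"band [{low}, {high}) Hz contains no PSD bins at this resolution")
    df = freqs[1] - freqs[0] if len(freqs) > 1 else 1.0
    return float(np.sum(psd[mask]) * df)


def spectral_power_ratio(values, fs: float = None, bands: SpectralBands = None,
                         kind: str = None) -> float:
    """psi = band power in F1 / band power in F2, via a Welch periodogram.

    Accepts a :class:`UniformSignal`/segment (fs taken from it) or a plain
    array plus ``fs``.  Bands above Nyquist are truncated there.
    """
    if hasattr(values, "fs"):
        fs = values.fs
        x = values.values
    else:
        x = np.asarray(values, dtype=float)
        if fs is None:
            raise InvalidArgumentError("fs required for array input")
    if bands is None:
        if kind not in DEFAULT_BANDS:
            raise InvalidArgumentError("provide bands or kind in {'ecg','bvp'}")
        f1, f2 = DEFAULT_BANDS[kind]
        bands = SpectralBands(f1, f2)
    freqs, psd = _welch_psd(x, fs)
    nyq = fs / 2
    f1 = (bands.F1[0], min(bands.F1[1], nyq))
    f2 = (bands.F2[0], min(bands.F2[1], nyq))
    p2 = band_power(freqs, psd, f2)
    if p2 < 1e-30:
        raise UndefinedRatioError("total power in F2 below machine tolerance")
    return band_power(freqs, psd, f1) / p2


def classify_cardiac(K: float, psi: float, kind: str,
                     k_ecg: float = K_THRESHOLD_ECG,
                     k_bvp: float = K_THRESHOLD_BVP,
                     psi_range=PSI_RANGE) -> tuple:
    """Good/bad flags: ECG needs K > 5, BVP needs K < 3.5; both need
    0.5 <= psi <= 0.8.  Inequalities on K are strict."""
    if kind == "ecg":
        k_good = K > k_ecg
    elif kind == "bvp":
        k_good = K < k_bvp
    else:
        raise InvalidArgumentError(f"kind must be ecg|bvp, got {kind!r}")
    psi_good = psi_range[0] <= psi <= psi_range[1]
    return bool(k_good), bool(psi_good)


def cardiac_sqi(signal: UniformSignal, kind: str = None,
                bands: SpectralBands = None) -> CardiacSQI:
    """Full cardiac-quality pipeline on a raw ECG or BVP signal.

    Resample to 128 Hz, band-pass [0.5, 50] Hz, z-score, cut into 5 s
    non-overlapping windows, compute K and psi per window, report means and
    threshold classification.  Windows where an SQI is undefined (constant
    slice) are excluded and counted.
    """
    kind = kind or signal.kind
    if kind not in ("ecg", "bvp"):
        raise InvalidArgumentError(f"kind must be ecg|bvp, got {kind!r}")
    if signal.duration < WINDOW_S:
        raise InvalidArgumentError(f"signal shorter than one {WINDOW_S} s window")
    if bands is None:
        bands = SpectralBands(*DEFAULT_BANDS[kind])

    prepped = standardize(filter_band(resample(signal, PIPELINE_FS), "band", PIPELINE_BAND))
    ks, psis, excluded = [], [], 0
    for seg in segment(prepped, WINDOW_S, 0.0):
        try:
            ks.append(kurtosis(seg))
            psis.append(spectral_power_ratio(seg, bands=bands))
        except (DegenerateSignalError, UndefinedRatioError):
            excluded += 1
    if not ks:
        raise DegenerateSignalError("every segment was degenerate")
    K, psi = float(np.mean(ks)), float(np.mean(psis))
    k_good, psi_good = classify_cardiac(K, psi, kind)
    return CardiacSQI(
        K_per_segment=np.asarray(ks), psi_per_segment=np.asarray(psis),
        K=K, psi=psi, n_segments=len(ks), n_excluded=excluded, kind=kind,
        K_good=k_good, psi_good=psi_good,
        params={"fs": PIPELINE_FS, "band": PIPELINE_BAND, "window_s": WINDOW_S,
                "F1": bands.F1, "F2": bands.F2})
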