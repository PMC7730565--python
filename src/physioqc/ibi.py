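"""Inter-beat-interval analysis.

From a detected beat series this module derives the IBI series (tachogram),
cleans it with the adaptive outlier detection (AOD) filter, validates
detections against a reference (precision, recall, eRMSE under a 0.5 s
pairing rule), computes the standard short-term HRV indicators (mean IBI,
RMSSD, relative HF power) and quantifies device agreement with Bland-Altman
percent-difference statistics.

AOD keeps a fixed-size cache of the last ``k`` valid IBI values; a beat is
valid when its IBI lies within ``[(1-phi)*median(cache), (1+phi)*median(cache)]``.
Valid IBIs enter the cache FIFO; after ``k`` consecutive invalid beats the
cache is re-initialized to the global median.  Defaults ``k=5``,
``phi=0.25``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .beats import BeatSeries
from .errors import InsufficientDataError, InvalidArgumentError

AOD_CACHE_SIZE = 5
AOD_SENSITIVITY = 0.25
PAIRING_TOL_S = 0.5
HF_BAND = (0.15, 0.4)
TOTAL_BAND = (0.04, 0.4)
TACHOGRAM_FS = 4.0


@dataclass(frozen=True)
class IBISeries:
    """Beat times with derived IBI values and per-beat validity flags.

    ``ibi_values[i] = beat_times[i+1] - beat_times[i]`` — the IBI is
    attributed to its terminating beat.  ``valid`` has one flag per beat; the
    first beat (which terminates no IBI) is always valid.
    """

    beat_times: np.ndarray
    ibi_values: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.beat_times, dtype=float)
        v = np.asarray(self.ibi_values, dtype=float)
        f = np.asarray(self.valid, dtype=bool)
        if v.size != t.size - 1 or f.size != t.size:
            raise InvalidArgumentError("need n beats, n-1 IBIs, n flags")
        if np.any(v <= 0):
            raise InvalidArgumentError("IBI values must be positive")
        object.__setattr__(self, "beat_times", t)
        object.__setattr__(self, "ibi_values", v)
        object.__setattr__(self, "valid", f)

    @property
    def valid_ibis(self) -> np.ndarray:
        """IBI values whose terminating beat is flagged valid."""
        return self.ibi_values[self.valid[1:]]


@dataclass(frozen=True)
class IBIComparison:
    """Beat-pairing validation counts and metrics."""

    nTP: int
    nFP: int
    nFN: int
    precision: float
    recall: float
    eRMSE: float  # seconds; NaN when undefined (no pairs)
    pairs: tuple  # (detected index, reference index)


@dataclass(frozen=True)
class HRVIndicators:
    mean_ibi: float
    rmssd: float
    hf_relative: float


@dataclass(frozen=True)
class BlandAltmanStats:
    """Percent-difference agreement statistics: 100 * (test - ref) / ref."""

    percent_diffs: np.ndarray
    means: np.ndarray  # per-pair means, the Bland-Altman x axis
    bias: float
    loa_low: float
    loa_high: float


def ibi_from_beats(beats) -> IBISeries:
    """Build the IBI series from beat times; all beats initially valid."""
    t = beats.beat_times if isinstance(beats, BeatSeries) else np.asarray(beats, float)
    if t.size < 2:
        raise InsufficientDataError("IBI series", "need at least 2 beats")
    return IBISeries(t, np.diff(t), np.ones(t.size, dtype=bool))


def aod_filter(ibi: IBISeries, k: int = AOD_CACHE_SIZE,
               phi: float = AOD_SENSITIVITY,
               reinit: str = "global-median") -> IBISeries:
    """Adaptive outlier detection on an IBI series.

    Sequential scan: beat ``i`` (i >= 1) is valid iff its IBI lies in
    ``[(1-phi) m, (1+phi) m]`` with ``m`` the median of the cache.  The cache
    starts filled with the global median of the series, valid IBIs push into
    it FIFO, and after ``k`` consecutive invalid beats it is re-initialized
    (``reinit='global-median'``) and the counter reset.  Beats are flagged,
    never deleted.
    """
    if not 0 < phi < 1:
        raise InvalidArgumentError("phi must lie in (0, 1)")
    if reinit != "global-median":
        raise InvalidArgumentError("only 'global-median' re-initialization is implemented")
    global_median = float(np.median(ibi.ibi_values))
    cache = [global_median] * k
    flags = np.ones(ibi.beat_times.size, dtype=bool)
    consecutive_invalid = 0
    for i, value in enumerate(ibi.ibi_values, start=1):
        m = float(np.median(cache))
        if (1 - phi) * m <= value <= (1 + phi) * m:
            flags[i] = True
            cache.pop(0)
            cache.append(value)
            consecutive_invalid = 0
        else:
            flags[i] = False
            consecutive_invalid += 1
            if consecutive_invalid >= k:
                cache = [global_median] * k
                consecutive_invalid = 0
    return IBISeries(ibi.beat_times, ibi.ibi_values, flags)


def pair_beats(detected, reference, tol: float = PAIRING_TOL_S):
    """One-to-one greedy nearest-distance matching under |bd - br| < tol.

    Candidate pairs are sorted by distance (ties: earlier reference beat
    wins) and assigned greedily, each beat used at most once.  Returns
    (pairs, nTP, nFP, nFN) with pairs as (detected index, reference index).
    """
    d = detected.beat_times if hasattr(detected, "beat_times") else np.asarray(detected, float)
    r = reference.beat_times if hasattr(reference, "beat_times") else np.asarray(reference, float)
    cands = []
    for i, td in enumerate(d):
        j0 = np.searchsorted(r, td - tol)
        j1 = np.searchsorted(r, td + tol)
        for j in range(j0, j1):
            dist = abs(td - r[j])
            if dist < tol:
                cands.append((dist, j, i))
    cands.sort()
    used_d, used_r, pairs = set(), set(), []
    for dist, j, i in cands:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((i, j))
    pairs.sort()
    nTP = len(pairs)
    return pairs, nTP, len(d) - nTP, len(r) - nTP


def compare_ibi(detected, reference, tol: float = PAIRING_TOL_S) -> IBIComparison:
    """Precision, recall and eRMSE of a detected beat series vs a reference.

    eRMSE is the RMS difference of paired IBI values, each IBI attributed to
    its terminating beat; an IBI enters the sum only when both of its
    endpoint beats are paired (to the corresponding reference endpoints), so
    the difference is well defined.
    """
    d = detected.beat_times if hasattr(detected, "beat_times") else np.asarray(detected, float)
    r = reference.beat_times if hasattr(reference, "beat_times") else np.asarray(reference, float)
    pairs, nTP, nFP, nFN = pair_beats(d, r, tol)
    precision = nTP / (nTP + nFP) if nTP + nFP else float("nan")
    recall = nTP / (nTP + nFN) if nTP + nFN else float("nan")
    match = dict(pairs)
    sq = []
    for i, j in pairs:
        if i >= 1 and j >= 1 and match.get(i - 1) == j - 1:
            sq.append(((d[i] - d[i - 1]) - (r[j] - r[j - 1])) ** 2)
    ermse = float(np.sqrt(np.mean(sq))) if sq else (0.0 if nTP else float("nan"))
    if nTP and not sq:
        ermse = float("nan")  # pairs exist but no IBI has both endpoints paired
    return IBIComparison(nTP, nFP, nFN, precision, recall, ermse, tuple(pairs))


def _successive_valid_diffs(ibi: IBISeries) -> np.ndarray:
    """Differences of adjacent IBIs where both IBIs are valid (a flagged beat
    breaks successiveness)."""
    ok = ibi.valid[1:]
    v = ibi.ibi_values
    both = ok[:-1] & ok[1:]
    return np.diff(v)[both]


def hrv_indicators(ibi: IBISeries, include_hf: bool = True,
                   hf_band=HF_BAND, total_band=TOTAL_BAND) -> HRVIndicators:
    """Mean IBI, RMSSD and relative HF power of an IBI series.

    Time-domain indicators use valid IBIs only (>= 10 required); RMSSD uses
    successive differences between adjacent valid IBIs.  HF relative power is
    the Welch power of the evenly resampled (4 Hz cubic-spline) mean-removed
    tachogram in [0.15, 0.4] Hz over the power in [0.04, 0.4] Hz; it needs a
    span of at least 60 s.  A zero-variance tachogram yields hf_relative 0.
    """
    vi = ibi.valid_ibis
    if vi.size < 10:
        raise InsufficientDataError("mean_ibi/rmssd", f"{vi.size} valid IBIs < 10")
    mean_ibi = float(np.mean(vi))
    diffs = _successive_valid_diffs(ibi)
    if diffs.size < 1:
        raise InsufficientDataError("rmssd", "no successive valid IBI pairs")
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))

    hf_rel = float("nan")
    if include_hf:
        vt = ibi.beat_times[1:][ibi.valid[1:]]
        span = vt[-1] - vt[0]
        if span < 60:
            raise InsufficientDataError("hf_relative", f"span {span:.1f} s < 60 s")
        spline = CubicSpline(vt, ibi.ibi_values[ibi.valid[1:]])
        t = np.arange(vt[0], vt[-1], 1 / TACHOGRAM_FS)
        tach = spline(t)
        tach = tach - np.mean(tach)
        nper = min(len(tach), int(120 * TACHOGRAM_FS))
        freqs, psd = sps.welch(tach, fs=TACHOGRAM_FS, window="hann",
                               nperseg=nper, noverlap=nper // 2)
        df = freqs[1] - freqs[0]
        p_hf = float(np.sum(psd[(freqs >= hf_band[0]) & (freqs < hf_band[1])]) * df)
        p_tot = float(np.sum(psd[(freqs >= total_band[0]) & (freqs < total_band[1])]) * df)
        if p_tot < 1e-18:
            warnings.warn("degenerate tachogram: no power in the HRV band")
            hf_rel = 0.0
        else:
            hf_rel = p_hf / p_tot
    return HRVIndicators(mean_ibi, rmssd, hf_rel)


def bland_altman_percent(test, ref) -> BlandAltmanStats:
    """Bland-Altman agreement on percent differences 100 * (test - ref) / ref.

    Bias is the mean percent difference; the limits of agreement are
    bias +/- 1.96 sd.
    """
    t = np.asarray(test, dtype=float)
    r = np.asarray(ref, dtype=float)
    if t.size != r.size or t.size < 2:
        raise InvalidArgumentError("need equal-length sequences of at least 2 pairs")
    zeros = np.flatnonzero(r == 0)
    if zeros.size:
        raise InvalidArgumentError(f"reference value is zero at pair(s) {zeros.tolist()}")
    pd_ = 100.0 * (t - r) / r
    bias = float(np.mean(pd_))
    sd = float(np.std(pd_, ddof=0))
    return BlandAltmanStats(pd_, (t + r) / 2, bias, bias - 1.96 * sd, bias + 1.96 * sd)
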