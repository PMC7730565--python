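"""Synthetic physiological signals with ground truth and injectable artifacts.

Generators for ECG, BVP and EDA whose outputs carry full ground-truth
annotations (beat times, SCR onsets, artifact intervals), so every pipeline
stage — beat detection, IBI validation, cardiac and EDA SQIs — can be tested
in closed loop without access to human recordings.

The waveforms are conventional morphology templates, not physiologically
validated simulations: an ECG beat is a sum of Gaussian P/Q/R/S/T deflections
around each R time; a BVP pulse is a fast half-cosine systolic upslope with
an exponential decay and a dicrotic bump; EDA is a tonic level plus drift,
renewal-timed skin-conductance responses (~2 s rise, ~6 s exponential
decay) and low-amplitude band-limited noise.  Each template was chosen so the quality metrics
respond with a controllable ground truth (spiky QRS -> high kurtosis, pulse
fundamental inside the BVP F1 band, SCR amplitudes straddling the 0.05 uS
activity floor).

Artifact injection reproduces the degradation modes seen on wearables:
band-limited motion-noise bursts, instantaneous step jumps, range
saturation, and flat dropouts.  All generators are pure functions of
(parameters, seed); one child random stream per signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InvalidArgumentError
from .signals import UniformSignal, filter_band

#: beats are laid down while t < duration - EDGE_MARGIN_S so the final
#: waveform complex fits inside the record
EDGE_MARGIN_S = 0.4

ARTIFACT_TYPES = ("motion_burst", "step_jump", "saturation_low",
                  "saturation_high", "dropout")

PROFILES = ("clinical", "wearable_wrist", "wearable_chest")


@dataclass(frozen=True)
class SyntheticSession:
    """A 300 s multi-signal bundle with ground truth."""

    signals: dict
    truth: dict
    seed: int
    profile: str
    phase: str


# ----------------------------------------------------------------------
# beat-time processes
# ----------------------------------------------------------------------

def _ibi_sequence(duration_s, mean_hr_bpm, rmssd_s, rng,
                  rsa_hz: float = 0.25, rsa_amp_s: float = 0.0):
    """Beat times from an autocorrelated IBI process.

    AR(1) fluctuations (rho = 0.5) with the innovation scale set so the
    expected RMSSD of the sequence equals ``rmssd_s``; optional sinusoidal
    respiratory modulation at ``rsa_hz``.  ``rmssd_s = 0`` gives an exact
    metronome.
    """
    if not 30 <= mean_hr_bpm <= 220:
        raise InvalidArgumentError("mean_hr_bpm must lie in [30, 220]")
    if duration_s < 10:
        raise InvalidArgumentError("duration_s must be >= 10 s")
    mean_ibi = 60.0 / mean_hr_bpm
    if rmssd_s < 0 or rmssd_s > 0.3 * mean_ibi:
        raise InvalidArgumentError(
            f"rmssd_s {rmssd_s} infeasible for mean IBI {mean_ibi:.3f} s")
    rho = 0.5
    sigma_w = rmssd_s * np.sqrt((1 + rho) / 2)
    times = []
    t = mean_ibi / 2
    e = 0.0
    while t < duration_s - EDGE_MARGIN_S:
        times.append(t)
        e = rho * e + (sigma_w * rng.standard_normal() if sigma_w > 0 else 0.0)
        ibi = mean_ibi + e + rsa_amp_s * np.sin(2 * np.pi * rsa_hz * t)
        ibi = max(ibi, 0.25)  # physiological floor
        t += ibi
    return np.asarray(times)


def _add_gaussian(wave, times, t_beat, offset, amp, width):
    wave += amp * np.exp(-0.5 * ((times - t_beat - offset) / width) ** 2)


def generate_ecg(duration_s: float, mean_hr_bpm: float = 60.0,
                 rmssd_s: float = 0.0, fs: float = 256.0, seed: int = 0,
                 noise_uV: float = 0.005, rsa_amp_s: float = 0.0):
    """Synthetic ECG in mV with known R-peak times.

    Returns ``(UniformSignal, beat_times)``.  R peaks are 1 mV Gaussians
    (sigma 10 ms) with Q/S troughs and low-amplitude P/T bumps; the noise
    floor is 40 Hz band-limited Gaussian noise plus slow baseline wander.
    """
    rng = np.random.default_rng(seed)
    beats = _ibi_sequence(duration_s, mean_hr_bpm, rmssd_s, rng, rsa_amp_s=rsa_amp_s)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    half = int(round(0.6 * fs))
    for tb in beats:
        c = int(round(tb * fs))
        lo, hi = max(0, c - half), min(n, c + half)
        w = t[lo:hi]
        seg = np.zeros(hi - lo)
        _add_gaussian(seg, w, tb, -0.170, 0.08, 0.025)   # P
        _add_gaussian(seg, w, tb, -0.025, -0.10, 0.008)  # Q
        _add_gaussian(seg, w, tb, 0.0, 1.00, 0.010)      # R
        _add_gaussian(seg, w, tb, 0.028, -0.30, 0.010)   # S
        _add_gaussian(seg, w, tb, 0.280, 0.20, 0.060)    # T
        wave[lo:hi] += seg
    noise = rng.standard_normal(n) * noise_uV
    sos = sps.butter(4, min(40.0, 0.45 * fs) / (fs / 2), output="sos")
    noise = sps.sosfiltfilt(sos, noise)
    wander = (0.04 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
              + 0.03 * np.sin(2 * np.pi * 0.07 * t + rng.uniform(0, 2 * np.pi)))
    sig = UniformSignal(wave + noise + wander, fs=fs, units="mV", kind="ecg")
    return sig, beats


def generate_bvp(duration_s: float, mean_hr_bpm: float = 72.0,
                 rmssd_s: float = 0.0, fs: float = 64.0, seed: int = 0,
                 noise: float = 0.01, rise_s: float = 0.08):
    """Synthetic BVP (a.u.) with known pulse-onset times.

    Each pulse: half-cosine systolic rise over ``rise_s`` (the first
    derivative peaks ``rise_s/2`` after onset), exponential diastolic decay
    (tau 0.22 s) and a dicrotic bump.  Returns ``(UniformSignal, onsets)``.
    """
    rng = np.random.default_rng(seed)
    onsets = _ibi_sequence(duration_s, mean_hr_bpm, rmssd_s, rng)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    span = int(round(1.2 * fs))
    tau = np.arange(span) / fs
    rise = tau < rise_s
    template = np.where(rise, 0.5 * (1 - np.cos(np.pi * tau / rise_s)),
                        np.exp(-(tau - rise_s) / 0.22))
    template += 0.12 * np.exp(-0.5 * ((tau - 0.35) / 0.05) ** 2)
    for tb in onsets:
        c = int(round(tb * fs))
        hi = min(n, c + span)
        if c < n:
            wave[c:hi] += template[:hi - c]
    out = wave + rng.standard_normal(n) * noise
    return UniformSignal(out, fs=fs, units="a.u.", kind="bvp"), onsets


def generate_eda(duration_s: float, tonic_level_uS: float = 5.0,
                 drift_uS_per_min: float = 0.1, scr_rate_per_min: float = 2.0,
                 scr_amp_uS: float = 0.5, fs: float = 4.0, seed: int = 0,
                 noise_uS: float = 0.005):
    """Synthetic EDA in uS with known SCR onsets and amplitudes.

    Tonic level + linear drift + skin-conductance responses (2 s half-cosine
    rise, 6 s exponential decay, amplitudes jittered +/-30% around
    ``scr_amp_uS``) + band-limited sensor noise.  SCR onsets follow a
    jittered renewal process (inter-event interval = mean x U(0.6, 1.4)):
    responses show refractory-like spacing, so the realized event count
    tracks ``scr_rate_per_min`` closely.  Returns ``(UniformSignal, truth)``
    with ``truth = {'onsets', 'amplitudes'}``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = tonic_level_uS + drift_uS_per_min / 60.0 * t
    onsets, amps = [], []
    if scr_rate_per_min > 0:
        mean_iv = 60.0 / scr_rate_per_min
        tt = mean_iv * rng.uniform(0.2, 1.0)
        while tt < duration_s - 5:
            onsets.append(tt)
            amps.append(scr_amp_uS * rng.uniform(0.7, 1.3))
            tt += mean_iv * rng.uniform(0.6, 1.4)
    span = int(round(30 * fs))
    tau = np.arange(span) / fs
    rise_s, decay_s = 2.0, 6.0
    shape = np.where(tau < rise_s, 0.5 * (1 - np.cos(np.pi * tau / rise_s)),
                     np.exp(-(tau - rise_s) / decay_s))
    for on, a in zip(onsets, amps):
        c = int(round(on * fs))
        hi = min(n, c + span)
        wave[c:hi] += a * shape[:hi - c]
    # sensor noise is band-limited (device anti-alias filtering): white noise
    # would make the scale-free normalized-derivative jump metric fire on
    # noise alone, which real smoothed conductance traces do not do
    noise = rng.standard_normal(n)
    sos = sps.butter(2, min(0.3, 0.4 * fs) / (fs / 2), output="sos")
    noise = sps.sosfiltfilt(sos, noise)
    noise *= noise_uS / max(np.std(noise), 1e-12)
    wave = wave + noise
    sig = UniformSignal(wave, fs=fs, units="uS", kind="eda")
    return sig, {"onsets": np.asarray(onsets), "amplitudes": np.asarray(amps)}


# ----------------------------------------------------------------------
# artifact injection
# ----------------------------------------------------------------------

def inject_artifacts(signal: UniformSignal, spec, seed: int = 0):
    """Inject wearable-style artifacts into a clean signal.

    ``spec`` is a list of ``(type, start_s, duration_s, magnitude)`` with
    type in ``motion_burst | step_jump | saturation_low | saturation_high |
    dropout``:

    * motion_burst — adds band-limited Gaussian noise of RMS ``magnitude``
      with tapered edges;
    * step_jump — adds a level shift of ``magnitude`` over the interval (a
      shift lasting to the end of the record is a single discontinuity; a
      shorter one steps back, creating two);
    * saturation_low / saturation_high — clamps the interval to the constant
      ``magnitude`` (e.g. 0 uS or a value above 60 uS);
    * dropout — replaces the interval with a hold of the last value.

    Returns ``(signal, annotations)``; annotations echo the spec with
    realized sample indices.  Saturation and dropout may not overlap.
    """
    rng = np.random.default_rng(seed)
    x = signal.values.copy()
    n = len(x)
    annotations = []
    clamped = np.zeros(n, dtype=bool)
    for art_type, start_s, duration_s, magnitude in spec:
        if art_type not in ARTIFACT_TYPES:
            raise InvalidArgumentError(f"unknown artifact type {art_type!r}")
        i0 = int(round((start_s - signal.t0) * signal.fs))
        i1 = int(round((start_s + duration_s - signal.t0) * signal.fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise InvalidArgumentError(
                f"artifact interval [{start_s}, {start_s + duration_s}) outside extent")
        if art_type == "motion_burst":
            m = i1 - i0
            hi_c = min(8.0, 0.45 * signal.fs)
            lo_c = min(0.5, hi_c / 4)
            sos = sps.butter(4, [lo_c / (signal.fs / 2), hi_c / (signal.fs / 2)],
                             btype="bandpass", output="sos")
            noise = sps.sosfiltfilt(sos, rng.standard_normal(max(m, 64)))[:m]
            noise = noise / max(np.std(noise), 1e-12) * magnitude
            taper = sps.windows.tukey(m, alpha=min(1.0, 2 * signal.fs / m))
            x[i0:i1] += noise * taper
        elif art_type == "step_jump":
            x[i0:i1] += magnitude
        elif art_type in ("saturation_low", "saturation_high"):
            if np.any(clamped[i0:i1]):
                raise InvalidArgumentError("overlapping saturation/dropout intervals")
            x[i0:i1] = magnitude
            clamped[i0:i1] = True
        elif art_type == "dropout":
            if np.any(clamped[i0:i1]):
                raise InvalidArgumentError("overlapping saturation/dropout intervals")
            x[i0:i1] = x[i0 - 1] if i0 > 0 else x[0]
            clamped[i0:i1] = True
        annotations.append({"type": art_type, "start_s": float(start_s),
                            "duration_s": float(duration_s),
                            "magnitude": float(magnitude),
                            "start_index": i0, "end_index": i1})
    return signal.with_values(x), annotations


# ----------------------------------------------------------------------
# full sessions
# ----------------------------------------------------------------------

#: per-profile generation parameters; the movement phase adds the listed
#: artifact load on top of the baseline signals
_PROFILE_PARAMS = {
    "clinical": {"ecg_fs": 256.0, "bvp_fs": 64.0, "eda_fs": 32.0,
                 "ecg_noise": 0.003, "bvp_noise": 0.005,
                 "movement": []},
    "wearable_chest": {"ecg_fs": 128.0, "bvp_fs": 64.0, "eda_fs": 4.0,
                       "ecg_noise": 0.01, "bvp_noise": 0.01,
                       "movement": [("ecg", "motion_burst", 60, 10, 0.15),
                                    ("ecg", "motion_burst", 180, 10, 0.15)]},
    "wearable_wrist": {"ecg_fs": 128.0, "bvp_fs": 64.0, "eda_fs": 4.0,
                       "ecg_noise": 0.008, "bvp_noise": 0.01,
                       "movement": [("bvp", "motion_burst", 40, 20, 2.5),
                                    ("bvp", "motion_burst", 120, 25, 3.0),
                                    ("bvp", "motion_burst", 220, 20, 2.5),
                                    ("eda", "motion_burst", 60, 15, 0.8),
                                    ("eda", "step_jump", 100, 200, 3.0),
                                    ("eda", "step_jump", 170, 130, -2.0),
                                    ("eda", "step_jump", 240, 60, 2.5)]},
}

SESSION_DURATION_S = 300.0


def generate_session(profile: str, phase: str, seed: int = 0) -> SyntheticSession:
    """A 300 s baseline or movement session for one device profile.

    All profiles produce ECG, BVP and EDA, with ECG and BVP driven by the
    same underlying inter-beat-interval process.  The movement phase raises heart rate and adds the profile's artifact
    load: heavy BVP/EDA motion corruption on the wrist wearable, mild ECG
    noise bursts on the chest wearable, none on the clinical reference.
    """
    if profile not in PROFILES:
        raise InvalidArgumentError(f"profile must be one of {PROFILES}")
    if phase not in ("baseline", "movement"):
        raise InvalidArgumentError("phase must be 'baseline' or 'movement'")
    p = _PROFILE_PARAMS[profile]
    hr = 70.0 if phase == "baseline" else 95.0
    streams = np.random.SeedSequence(seed).spawn(4)
    s_ecg, s_bvp, s_eda, s_art = (int(s.generate_state(1)[0] % (2 ** 31)) for s in streams)

    ecg, beats = generate_ecg(SESSION_DURATION_S, hr, rmssd_s=0.03,
                              fs=p["ecg_fs"], seed=s_ecg, noise_uV=p["ecg_noise"])
    # same seed -> same underlying IBI process drives ECG and BVP
    bvp, onsets = generate_bvp(SESSION_DURATION_S, hr, rmssd_s=0.03,
                               fs=p["bvp_fs"], seed=s_ecg, noise=p["bvp_noise"])
    eda, scr_truth = generate_eda(SESSION_DURATION_S, fs=p["eda_fs"], seed=s_eda)

    signals = {"ecg": ecg, "bvp": bvp, "eda": eda}
    artifacts = []
    if phase == "movement":
        by_kind: dict[str, list] = {}
        for kind, art_type, start, dur, mag in p["movement"]:
            by_kind.setdefault(kind, []).append((art_type, start, dur, mag))
        for kind, specs in by_kind.items():
            signals[kind], anns = inject_artifacts(signals[kind], specs, seed=s_art)
            artifacts.extend({**a, "kind": kind} for a in anns)
    truth = {"ecg_beats": beats, "bvp_onsets": onsets,
             "scr_onsets": scr_truth["onsets"],
             "scr_amplitudes": scr_truth["amplitudes"],
             "artifacts": artifacts}
    return SyntheticSession(signals=signals, truth=truth, seed=seed,
                            profile=profile, phase=phase)
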