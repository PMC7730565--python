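import numpy as np
import pytest

import physioqc as pq


@pytest.fixture(scope="session")
def clean_ecg_60bpm():
    """300 s clean metronome ECG at 60 bpm with ground-truth R times."""
    return pq.generate_ecg(300, 60, rmssd_s=0.0, seed=7)


@pytest.fixture(scope="session")
def clean_ecg_hrv():
    """300 s ECG with physiological variability (RMSSD 30 ms)."""
    return pq.generate_ecg(300, 60, rmssd_s=0.03, seed=11)


@pytest.fixture(scope="session")
def clean_bvp():
    """60 s clean metronome BVP at 72 bpm with ground-truth onsets."""
    return pq.generate_bvp(60, 72, rmssd_s=0.0, seed=3)


@pytest.fixture(scope="session")
def clean_eda():
    """300 s EDA with ~10 SCRs of 0.5 uS."""
    return pq.generate_eda(300, scr_rate_per_min=2.0, scr_amp_uS=0.5, seed=5)


@pytest.fixture(scope="session")
def tonic_eda():
    """300 s smooth tonic-only EDA (no SCRs)."""
    sig, _ = pq.generate_eda(300, scr_rate_per_min=0.0, seed=5)
    return sig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def sine_signal(freq_hz, fs, duration_s, amp=1.0, kind="other"):
    t = np.arange(int(duration_s * fs)) / fs
    return pq.UniformSignal(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs, kind=kind)
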