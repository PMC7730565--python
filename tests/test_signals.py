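"""Core container and preprocessing primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import physioqc as pq
from physioqc.errors import DegenerateSignalError, InvalidArgumentError

from conftest import sine_signal


class TestUniformSignal:
    def test_invariants(self):
        s = pq.UniformSignal([1.0, 2.0, 3.0], fs=2.0, t0=1.0)
        assert s.duration == 1.5
        np.testing.assert_allclose(s.times, [1.0, 1.5, 2.0])

    @pytest.mark.parametrize("kwargs", [
        {"values": [], "fs": 1.0},
        {"values": [1.0], "fs": 0.0},
        {"values": [1.0], "fs": 1.0, "kind": "emg"},
    ])
    def test_rejects_bad_construction(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            pq.UniformSignal(**kwargs)


class TestResample:
    def test_duration_bookkeeping(self):
        s = pq.UniformSignal(np.zeros(40), fs=4.0)
        out = pq.resample(s, 128.0)
        assert out.fs == 128.0
        assert len(out) == 1280

    def test_downsampled_sinusoid_matches_closed_form(self):
        s = sine_signal(1.0, 2048.0, 10.0)
        out = pq.resample(s, 128.0)
        t = np.arange(len(out)) / 128.0
        # ignore filter edge transients
        core = slice(64, -64)
        err = np.max(np.abs(out.values[core] - np.sin(2 * np.pi * t)[core]))
        assert err < 1e-3

    def test_identity(self):
        s = sine_signal(1.0, 64.0, 5.0)
        out = pq.resample(s, 64.0)
        np.testing.assert_allclose(out.values, s.values, atol=1e-9)

    def test_round_trip_preserves_bandlimited_content(self):
        s = sine_signal(2.0, 64.0, 20.0)
        back = pq.resample(pq.resample(s, 256.0), 64.0)
        core = slice(32, -32)
        rms = np.sqrt(np.mean((back.values[core] - s.values[core]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(s.values[core] ** 2))

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(InvalidArgumentError):
            pq.resample(sine_signal(1.0, 64.0, 5.0), 0.0)


class TestFilterBand:
    def test_bandpass_attenuates_out_of_band_tone(self):
        s = sine_signal(60.0, 128.0, 10.0)
        # 60 Hz is within one octave of the 50 Hz edge but near Nyquist;
        # push it through the cardiac band and measure attenuation
        out = pq.filter_band(s, "band", (0.5, 50.0))
        assert np.sqrt(np.mean(out.values ** 2)) < 0.1 * np.sqrt(np.mean(s.values ** 2))

    def test_dc_removed_by_bandpass(self):
        s = sine_signal(10.0, 128.0, 60.0)
        offset = 7.0
        out = pq.filter_band(s.with_values(s.values + offset), "band", (0.5, 50.0))
        assert abs(np.mean(out.values)) < 1e-3 * offset

    def test_passband_identity(self):
        s = sine_signal(0.1, 4.0, 120.0)
        out = pq.filter_band(s, "low", 1.5)
        core = slice(40, -40)
        err = np.sqrt(np.mean((out.values[core] - s.values[core]) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(s.values[core] ** 2))

    def test_linearity(self, rng):
        s = pq.UniformSignal(rng.standard_normal(512), fs=64.0)
        a = 3.7
        out1 = pq.filter_band(s.with_values(a * s.values), "band", (1.0, 20.0))
        out2 = pq.filter_band(s, "band", (1.0, 20.0))
        np.testing.assert_allclose(out1.values, a * out2.values, rtol=1e-9, atol=1e-12)

    def test_rejects_cutoff_beyond_nyquist(self):
        with pytest.raises(InvalidArgumentError):
            pq.filter_band(sine_signal(1.0, 64.0, 5.0), "low", 32.0)


class TestStandardize:
    def test_moments(self):
        s = pq.UniformSignal([1.0, 2.0, 3.0], fs=1.0)
        out = pq.standardize(s)
        assert abs(np.mean(out.values)) < 1e-9
        assert abs(np.std(out.values) - 1) < 1e-9
        assert out.units == "z-units"

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            pq.standardize(pq.UniformSignal(np.full(10, 2.0), fs=1.0))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50))
    def test_idempotence(self, values):
        if np.std(values) < 1e-6:
            return
        s = pq.UniformSignal(values, fs=1.0)
        once = pq.standardize(s)
        twice = pq.standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestSegment:
    @pytest.mark.parametrize("duration,width,overlap,expected", [
        (300.0, 5.0, 0.0, 60),
        (300.0, 20.0, 0.0, 15),
        (10.0, 1.0, 0.5, 19),
    ])
    def test_counts(self, duration, width, overlap, expected):
        s = pq.UniformSignal(np.zeros(int(duration * 32)), fs=32.0)
        segs = pq.segment(s, width, overlap)
        assert len(segs) == expected

    def test_nonoverlapping_partition_is_exact(self):
        s = pq.UniformSignal(np.arange(300 * 4, dtype=float), fs=4.0)
        segs = pq.segment(s, 20.0, 0.0)
        covered = np.concatenate([g.values for g in segs])
        np.testing.assert_array_equal(covered, s.values[: len(covered)])
        assert len(covered) == len(segs) * round(20.0 * 4)

    def test_too_short_signal_warns_and_returns_empty(self):
        s = pq.UniformSignal(np.zeros(8), fs=4.0)
        with pytest.warns(UserWarning):
            assert pq.segment(s, 5.0, 0.0) == []


class TestAccelerationModule:
    def test_three_four_five(self):
        mk = lambda v: pq.UniformSignal(np.full(5, float(v)), fs=32.0, kind="acc")
        out = pq.acceleration_module(mk(3), mk(4), mk(0))
        np.testing.assert_allclose(out.values, 5.0)

    def test_matches_per_sample_norm(self, rng):
        axes = [pq.UniformSignal(rng.standard_normal(100), fs=32.0, kind="acc")
                for _ in range(3)]
        out = pq.acceleration_module(*axes)
        brute = [np.sqrt(sum(a.values[i] ** 2 for a in axes)) for i in range(100)]
        np.testing.assert_allclose(out.values, brute)
        for a in axes:
            assert np.all(out.values >= np.abs(a.values) - 1e-12)

    def test_rejects_mismatched_axes(self):
        a = pq.UniformSignal(np.zeros(10), fs=32.0)
        b = pq.UniformSignal(np.zeros(11), fs=32.0)
        with pytest.raises(InvalidArgumentError):
            pq.acceleration_module(a, a, b)


class TestSplitSessions:
    def test_baseline_movement_split(self):
        s = pq.UniformSignal(np.arange(600 * 4, dtype=float), fs=4.0)
        markers = pq.SessionMarkers((("baseline_start", 0.0), ("baseline_end", 300.0),
                                     ("movement_start", 300.0), ("movement_end", 600.0)))
        out = pq.split_sessions(s, markers)
        assert set(out) == {"baseline", "movement"}
        assert out["baseline"].duration == pytest.approx(300.0)
        assert out["movement"].t0 == pytest.approx(300.0)
        joined = np.concatenate([out["baseline"].values, out["movement"].values])
        np.testing.assert_array_equal(joined, s.values)

    def test_non_integer_marker_rounds_to_sample(self):
        s = pq.UniformSignal(np.zeros(100), fs=4.0)
        out = pq.split_sessions(s, pq.SessionMarkers(
            (("a_start", 0.0), ("a_end", 10.13))))
        assert abs(len(out["a"]) - 10.13 * 4) <= 1

    def test_marker_outside_extent_rejected(self):
        s = pq.UniformSignal(np.zeros(100), fs=4.0)
        with pytest.raises(InvalidArgumentError):
            pq.split_sessions(s, pq.SessionMarkers(
                (("a_start", 0.0), ("a_end", 60.0))))
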