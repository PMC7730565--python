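"""IBI derivation, AOD outlier filtering, beat-pairing validation, HRV,
Bland-Altman agreement."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

import physioqc as pq
from physioqc.errors import InsufficientDataError, InvalidArgumentError


def beats_from_ibis(ibis, t0=0.0):
    return np.concatenate(([t0], t0 + np.cumsum(ibis)))


class TestIbiFromBeats:
    def test_unit_spacing(self):
        s = pq.ibi_from_beats(np.array([0.0, 1.0, 2.0, 3.0]))
        np.testing.assert_allclose(s.ibi_values, [1.0, 1.0, 1.0])
        assert np.all(s.valid)

    def test_irregular_spacing(self):
        s = pq.ibi_from_beats(np.array([0.0, 0.8, 1.7]))
        np.testing.assert_allclose(s.ibi_values, [0.8, 0.9])

    def test_cumsum_round_trip(self, rng):
        t = np.cumsum(rng.uniform(0.5, 1.2, 50)) + 3.0
        s = pq.ibi_from_beats(t)
        np.testing.assert_allclose(t[0] + np.cumsum(s.ibi_values), t[1:], atol=1e-12)

    def test_requires_two_beats(self):
        with pytest.raises(InsufficientDataError):
            pq.ibi_from_beats(np.array([1.0]))


class TestAODFilter:
    def test_constant_ibis_all_valid(self):
        s = pq.aod_filter(pq.ibi_from_beats(beats_from_ibis([0.8] * 20)))
        assert np.all(s.valid)

    def test_single_outlier_flagged(self):
        # median 0.8 -> interval [0.6, 1.0]; the 1.2 is the only invalid IBI
        ibis = [0.8] * 9 + [1.2] + [0.8] * 9
        s = pq.aod_filter(pq.ibi_from_beats(beats_from_ibis(ibis)))
        expected = np.array([v != 1.2 for v in ibis])
        np.testing.assert_array_equal(s.valid[1:], expected)

    def test_cache_reinit_after_k_consecutive_invalid(self):
        # plateau shift 0.8 -> 1.2: the first 5 of the new plateau are
        # rejected against the old cache; re-init to the global median (1.0)
        # admits the rest
        ibis = [0.8] * 20 + [1.2] * 20
        s = pq.aod_filter(pq.ibi_from_beats(beats_from_ibis(ibis)))
        flags = s.valid[1:]
        assert np.all(flags[:20])
        np.testing.assert_array_equal(flags[20:25], [False] * 5)
        assert np.all(flags[25:])

    def test_deterministic_rerun(self, rng):
        ibis = rng.uniform(0.5, 1.5, 100)
        series = pq.ibi_from_beats(beats_from_ibis(ibis))
        f1 = pq.aod_filter(series)
        f2 = pq.aod_filter(series)
        np.testing.assert_array_equal(f1.valid, f2.valid)

    def test_beats_retained_not_deleted(self):
        ibis = [0.8] * 9 + [1.2] + [0.8] * 9
        s = pq.aod_filter(pq.ibi_from_beats(beats_from_ibis(ibis)))
        assert len(s.beat_times) == len(ibis) + 1

    def test_phi_bounds(self):
        series = pq.ibi_from_beats(beats_from_ibis([0.8] * 5))
        with pytest.raises(InvalidArgumentError):
            pq.aod_filter(series, phi=1.5)


def _optimal_ntp(d, r, tol=0.5):
    """Maximum-cardinality matching oracle for pairing validation."""
    rows, cols = [], []
    for i, td in enumerate(d):
        for j, tr in enumerate(r):
            if abs(td - tr) < tol:
                rows.append(i)
                cols.append(j)
    if not rows:
        return 0
    m = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(d), len(r)))
    return int(np.sum(maximum_bipartite_matching(m, perm_type="column") >= 0))


class TestPairBeats:
    def test_identical_series(self):
        t = np.arange(100, dtype=float)
        _, ntp, nfp, nfn = pq.pair_beats(t, t)
        assert (ntp, nfp, nfn) == (100, 0, 0)

    def test_missing_beat_counted_as_fn(self):
        ref = np.arange(11, dtype=float)
        det = np.delete(ref, 5)
        _, ntp, nfp, nfn = pq.pair_beats(det, ref)
        assert (ntp, nfp, nfn) == (10, 0, 1)

    def test_exact_tolerance_shift_matches_nothing(self):
        ref = np.arange(10, dtype=float)
        _, ntp, nfp, nfn = pq.pair_beats(ref + 0.5, ref)
        assert ntp == 0 and nfp == 10 and nfn == 10

    def test_swap_symmetry(self, rng):
        d = np.sort(rng.uniform(0, 60, 40))
        r = np.sort(rng.uniform(0, 60, 50))
        _, ntp1, nfp1, nfn1 = pq.pair_beats(d, r)
        _, ntp2, nfp2, nfn2 = pq.pair_beats(r, d)
        assert ntp1 == ntp2 and nfp1 == nfn2 and nfn1 == nfp2

    def test_greedy_matches_optimal_on_beat_like_series(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.integers(5, 21)
            ref = np.cumsum(rng.uniform(0.6, 1.2, n))
            det = ref + rng.uniform(-0.2, 0.2, n)
            det = det[rng.random(n) > 0.2]
            det = np.unique(np.concatenate(
                [det, rng.uniform(0, ref[-1], rng.integers(0, 4))]))
            _, ntp, _, _ = pq.pair_beats(det, ref)
            assert ntp == _optimal_ntp(det, ref), f"seed {seed}"


class TestCompareIbi:
    def test_identical_series(self):
        t = np.arange(50, dtype=float)
        c = pq.compare_ibi(t, t)
        assert c.precision == 1.0 and c.recall == 1.0 and c.eRMSE == 0.0

    def test_common_shift_leaves_ibis_unchanged(self):
        ref = np.arange(50, dtype=float)
        c = pq.compare_ibi(ref + 0.010, ref)
        assert c.precision == 1.0 and c.recall == 1.0
        assert c.eRMSE == pytest.approx(0.0, abs=1e-12)

    def test_alternating_jitter_closed_form(self):
        ref = np.arange(50, dtype=float)
        det = ref + 0.010 * np.where(np.arange(50) % 2 == 0, 1.0, -1.0)
        c = pq.compare_ibi(det, ref)
        # every IBI is off by +/- 0.02 s
        assert c.eRMSE == pytest.approx(0.020, abs=1e-12)

    def test_recall_never_increases_under_deletion(self, rng):
        ref = np.cumsum(rng.uniform(0.7, 1.1, 60))
        det = ref.copy()
        prev_recall = 1.0
        for frac in (0.1, 0.3, 0.5):
            keep = rng.random(len(ref)) > frac
            c = pq.compare_ibi(ref[keep], ref)
            assert c.recall <= prev_recall + 1e-12
            prev_recall = c.recall

    def test_precision_never_increases_with_spurious_beats(self, rng):
        ref = np.cumsum(rng.uniform(0.7, 1.1, 60))
        prev_precision = 1.0
        for n_extra in (5, 15, 30):
            extra = rng.uniform(0, ref[-1], n_extra)
            det = np.unique(np.concatenate([ref, extra]))
            c = pq.compare_ibi(det, ref)
            assert c.precision <= prev_precision + 1e-12
            prev_precision = c.precision


class TestHRVIndicators:
    def test_constant_ibis(self):
        beats = np.arange(0, 200, 0.8)
        h = pq.hrv_indicators(pq.ibi_from_beats(beats))
        assert h.mean_ibi == pytest.approx(0.8, abs=1e-9)
        assert h.rmssd == pytest.approx(0.0, abs=1e-9)

    def test_alternating_ibis_rmssd_closed_form(self):
        ibis = np.tile([0.8, 0.9], 60)
        beats = np.concatenate(([0.0], np.cumsum(ibis)))
        h = pq.hrv_indicators(pq.ibi_from_beats(beats), include_hf=False)
        assert h.rmssd == pytest.approx(0.1, abs=1e-12)

    def test_respiratory_modulation_concentrates_hf_power(self):
        beats = [0.0]
        t = 0.0
        while t < 300:
            t += 0.8 + 0.05 * np.sin(2 * np.pi * 0.25 * t)
            beats.append(t)
        h = pq.hrv_indicators(pq.ibi_from_beats(np.array(beats)))
        assert h.hf_relative >= 0.9

    def test_invalid_ibis_excluded_from_mean(self):
        ibis = [0.8] * 9 + [1.2] + [0.8] * 9
        s = pq.aod_filter(pq.ibi_from_beats(beats_from_ibis(ibis)))
        h = pq.hrv_indicators(s, include_hf=False)
        assert h.mean_ibi == pytest.approx(0.8, abs=1e-9)

    def test_insufficient_data_names_indicator(self):
        with pytest.raises(InsufficientDataError, match="hf_relative"):
            pq.hrv_indicators(pq.ibi_from_beats(np.arange(0, 20, 0.8)))


class TestBlandAltman:
    def test_identical_sequences(self):
        x = np.array([0.8, 0.9, 1.0])
        ba = pq.bland_altman_percent(x, x)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_scale_offset(self):
        ref = np.array([0.8, 0.9, 1.0, 1.1])
        ba = pq.bland_altman_percent(1.10 * ref, ref)
        assert ba.bias == pytest.approx(10.0, abs=1e-9)
        assert ba.loa_high - ba.loa_low == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_recomputation(self, rng):
        ref = rng.uniform(0.5, 1.5, 30)
        test = ref * rng.uniform(0.9, 1.1, 30)
        ba = pq.bland_altman_percent(test, ref)
        pd_ = 100 * (test - ref) / ref
        assert ba.bias == pytest.approx(np.mean(pd_), abs=1e-12)
        assert ba.loa_high == pytest.approx(np.mean(pd_) + 1.96 * np.std(pd_), abs=1e-12)
        assert ba.loa_low + ba.loa_high == pytest.approx(2 * ba.bias, abs=1e-9)

    def test_zero_reference_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pq.bland_altman_percent([1.0, 2.0], [1.0, 0.0])
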