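"""Power trend, movmad, seizure centering, segment extraction, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hasdetect.core import EegEvent, EegRecord, GroundTruth
from hasdetect.trend import (
    center_seizure,
    compute_power_trend,
    extract_segment,
    movmad,
    sample_non_has,
)

FS = 256


def brute_movmad(x: np.ndarray, w: int) -> np.ndarray:
    """Independent oracle: direct median-of-absolute-deviations per window."""
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - w // 2)
        hi = min(n, i + (w - 1) // 2 + 1)
        win = x[lo:hi]
        out[i] = np.median(np.abs(win - np.median(win)))
    return out


def sine_record(freq, amplitude, duration_s, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return EegRecord(samples=amplitude * np.sin(2 * np.pi * freq * t), fs=fs)


class TestPowerTrend:
    def test_doubling_amplitude_adds_12dB(self):
        """Power scales with amplitude squared: +20*log10(4) ~ 12.04 dB."""
        t1 = compute_power_trend(sine_record(10, 1.0, 180))
        t2 = compute_power_trend(sine_record(10, 2.0, 180))
        np.testing.assert_allclose(
            t2.values - t1.values, 20 * np.log10(4.0), atol=1e-6
        )

    def test_out_of_band_tone_near_noise_floor(self):
        in_band = compute_power_trend(sine_record(10, 1.0, 120))
        out_band = compute_power_trend(sine_record(30, 1.0, 120))
        assert np.all(in_band.values - out_band.values >= 60.0)

    def test_partial_minute_dropped(self):
        trend = compute_power_trend(sine_record(10, 1.0, 61))
        assert trend.n_bins == 1

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="minute"):
            compute_power_trend(sine_record(10, 1.0, 59))


class TestMovmad:
    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=3, max_size=120
        ),
        window=st.integers(min_value=2, max_value=60),
    )
    def test_matches_bruteforce_oracle(self, data, window):
        x = np.asarray(data)
        np.testing.assert_allclose(
            movmad(x, window), brute_movmad(x, window), rtol=0, atol=1e-12
        )

    def test_matches_oracle_at_operating_window(self):
        """Exact agreement at the production window size (8000)."""
        rng = np.random.default_rng(0)
        x = np.abs(rng.standard_normal(20_000)) ** 10
        np.testing.assert_array_equal(movmad(x, 8000), brute_movmad(x, 8000))


class TestCentering:
    def test_recovers_known_center_within_one_second(self, burst_record):
        rec, true_center = burst_record(seed=42)
        trace = center_seizure(rec, true_center // (60 * FS))
        assert abs(trace.center_sample - true_center) / FS <= 1.0

    def test_short_burst_center_stays_inside_burst_core(self):
        """A 30 s burst is shorter than the 31 s movmad window, so the
        center of weight is only defined to within the window overlap; the
        chosen center must still fall well inside the burst."""
        from hasdetect.synth import generate_background, generate_has_event

        bg = generate_background(300, "term", seed=11, rms_uV=5.0)
        x = bg.samples.copy()
        wav = generate_has_event(30, 100.0, (0.5, 4.0), FS, seed=12)
        onset = int(130 * FS)
        x[onset : onset + wav.size] += wav
        rec = EegRecord(samples=x, fs=FS)
        trace = center_seizure(rec, (onset + wav.size // 2) // (60 * FS))
        quarter = wav.size // 4
        assert onset + quarter <= trace.center_sample <= onset + 3 * quarter

    def test_flat_line_falls_back_to_excerpt_midpoint(self):
        rec = EegRecord(samples=np.zeros(3 * 60 * FS), fs=FS)
        trace = center_seizure(rec, 1)
        mid = trace.excerpt_start + trace.sig_1.size // 2
        assert trace.center_sample == mid

    def test_two_identical_bursts_tie_breaks_to_first(self):
        # both bursts interior to the excerpt (30-150 s), away from the
        # shrinking edge windows, so their movmad plateaus tie exactly
        x = np.zeros(4 * 60 * FS)
        burst = np.sin(2 * np.pi * 3 * np.arange(10 * FS) / FS) * 100
        first, second = 60 * FS, 105 * FS
        x[first : first + burst.size] += burst
        x[second : second + burst.size] += burst
        rec = EegRecord(samples=x, fs=FS)
        trace = center_seizure(rec, 1)
        assert first <= trace.center_sample < second

    def test_scale_invariance(self, burst_record):
        """Positive rescaling must not move the chosen center."""
        rec, true_center = burst_record(seed=5)
        marked = true_center // (60 * FS)
        c1 = center_seizure(rec, marked).center_sample
        scaled = EegRecord(samples=rec.samples * 37.5, fs=FS)
        c2 = center_seizure(scaled, marked).center_sample
        assert c1 == c2

    def test_trace_lengths_and_center_inside_excerpt(self, burst_record):
        rec, true_center = burst_record(seed=6)
        trace = center_seizure(rec, true_center // (60 * FS))
        assert trace.sig_1.size == trace.sig_2.size == trace.sig_3.size
        assert (
            trace.excerpt_start
            <= trace.center_sample
            < trace.excerpt_start + trace.sig_1.size
        )

    def test_centering_idempotence(self, burst_record):
        """Re-centering on the found center's minute barely moves it."""
        rec, true_center = burst_record(seed=9)
        c1 = center_seizure(rec, true_center // (60 * FS)).center_sample
        c2 = center_seizure(rec, c1 // (60 * FS)).center_sample
        assert abs(c2 - c1) <= 8000 // 2

    def test_marked_minute_outside_record_rejected(self):
        rec = EegRecord(samples=np.zeros(2 * 60 * FS), fs=FS)
        with pytest.raises(ValueError, match="outside"):
            center_seizure(rec, 5)


class TestExtractSegment:
    def test_window_convention_on_ramp(self):
        rec = EegRecord(samples=np.arange(100, dtype=float), fs=FS)
        seg = extract_segment(rec, 10, L=4)
        np.testing.assert_array_equal(seg.samples, [8, 9, 10, 11])
        assert not seg.padded

    def test_canonical_length_duration(self):
        rec = EegRecord(samples=np.zeros(60_000), fs=FS)
        seg = extract_segment(rec, 30_000, L=51_302)
        assert seg.length == 51_302
        assert round(seg.length / FS / 60, 2) == 3.34

    def test_edge_windows_zero_padded_and_flagged(self):
        rec = EegRecord(samples=np.ones(1000), fs=FS)
        seg = extract_segment(rec, 0, L=100)
        assert seg.length == 100
        assert seg.padded
        np.testing.assert_array_equal(seg.samples[:50], 0.0)
        np.testing.assert_array_equal(seg.samples[50:], 1.0)

    @settings(max_examples=25, deadline=None)
    @given(center=st.integers(-50, 1050), L=st.integers(1, 200))
    def test_length_always_exact(self, center, L):
        rec = EegRecord(samples=np.ones(1000), fs=FS)
        assert extract_segment(rec, center, L=L).length == L


class TestSampleNonHas:
    @staticmethod
    def _truth_with(intervals, animal="a", channel="left"):
        truth = GroundTruth()
        for onset, offset in intervals:
            truth.add(
                animal,
                channel,
                EegEvent("HAS", onset, offset, (onset + offset) // 2),
            )
        return truth

    def test_windows_never_intersect_has_intervals(self):
        rng = np.random.default_rng(0)
        rec = EegRecord(
            samples=rng.standard_normal(200_000), fs=FS, animal_id="a", channel="left"
        )
        intervals = [(30_000, 40_000), (100_000, 110_000)]
        truth = self._truth_with(intervals)
        segs = sample_non_has(rec, truth, n=100, L=2560, seed=1)
        assert len(segs) == 100
        for seg in segs:
            lo = seg.center_sample - 2560 // 2
            hi = seg.center_sample + (2560 + 1) // 2
            for onset, offset in intervals:
                assert hi <= onset or lo >= offset  # exhaustive interval check
            assert lo >= 0 and hi <= rec.n_samples

    def test_fully_covered_record_rejected(self):
        rec = EegRecord(
            samples=np.zeros(10_000), fs=FS, animal_id="a", channel="left"
        )
        truth = self._truth_with([(0, 10_000)])
        with pytest.raises(ValueError, match="non-HAS"):
            sample_non_has(rec, truth, n=1, L=256, seed=0)

    def test_fixed_seed_reproduces_selection(self):
        rec = EegRecord(
            samples=np.zeros(50_000), fs=FS, animal_id="a", channel="left"
        )
        truth = GroundTruth()
        a = sample_non_has(rec, truth, n=10, L=1000, seed=3)
        b = sample_non_has(rec, truth, n=10, L=1000, seed=3)
        assert [s.center_sample for s in a] == [s.center_sample for s in b]
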