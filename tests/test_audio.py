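"""Click detection, clock synchronization, peri-event histograms and
context attribution."""

import numpy as np
import pytest

import neoapnea as na
from neoapnea.audio import AudioTrace, fit_sync, peri_event_histogram


def _audio_with_bursts(burst_times, fs=50_000.0, duration=5.0,
                       amp=0.4, noise=0.003, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise, int(duration * fs))
    n = int(0.0005 * fs)
    for t in burst_times:
        i = int(t * fs)
        x[i:i + n] += amp * rng.standard_normal(n)
    return AudioTrace(samples=x, sample_rate=fs)


class TestDetectClicks:
    def test_three_bursts_detected_at_programmed_times(self):
        times = [1.0, 2.5, 4.0]
        clicks = na.detect_clicks(_audio_with_bursts(times))
        assert len(clicks) == 3
        for c, t in zip(clicks, times):
            assert c.time == pytest.approx(t, abs=5e-4)
            assert c.duration < 0.002
            assert c.energy_db > 10

    def test_pure_tone_rejected(self):
        fs = 50_000.0
        t = np.arange(int(5 * fs)) / fs
        rng = np.random.default_rng(1)
        x = rng.normal(0, 0.003, t.size)
        burst = (t > 2.0) & (t < 2.1)
        x[burst] += 0.3 * np.sin(2 * np.pi * 17_000 * t[burst])
        assert na.detect_clicks(AudioTrace(samples=x, sample_rate=fs)) == []

    def test_silent_audio_gives_empty_list(self):
        silent = AudioTrace(samples=np.zeros(100_000), sample_rate=50_000.0)
        assert na.detect_clicks(silent) == []

    def test_low_sample_rate_rejected(self):
        a = AudioTrace(samples=np.zeros(1000), sample_rate=8000.0)
        with pytest.raises(ValueError, match="sample rate"):
            na.detect_clicks(a)

    def test_exclusion_windows(self):
        clicks = na.detect_clicks(_audio_with_bursts([1.0, 2.5]),
                                  exclude_windows=[(2.4, 2.6)])
        assert len(clicks) == 1 and clicks[0].time == pytest.approx(1.0, abs=1e-3)

    def test_recall_and_fdr_on_simulated_recording(self, wt_audio_recording,
                                                   wt_audio_result):
        _, _, truth = wt_audio_recording
        det = np.array([c.time for c in wt_audio_result.clicks])
        tru = np.sort(truth.clicks.time_s.to_numpy())
        assert len(det) > 0 and len(tru) > 0
        fp = (np.abs(det[:, None] - tru[None, :]).min(axis=1) > 0.002).sum()
        missed = (np.abs(tru[:, None] - det[None, :]).min(axis=1) > 0.002).sum()
        assert missed / len(tru) <= 0.02       # recall >= 0.98
        assert fp / max(len(det), 1) <= 0.02   # FDR <= 0.02


class TestSync:
    def test_linear_solve_example(self):
        m = fit_sync((0.0, 600.0), (0.0, 600.030))
        assert m.drift_ppm == pytest.approx(50.0)
        assert m.offset == pytest.approx(0.0)
        assert m.audio_to_pressure(600.030) == pytest.approx(600.0)

    def test_identity_clocks(self):
        m = fit_sync((1.0, 500.0), (1.0, 500.0))
        assert m.drift_ppm == pytest.approx(0.0)
        assert m.audio_to_pressure(123.0) == pytest.approx(123.0)

    def test_missing_mark_names_channel(self):
        with pytest.raises(ValueError, match="audio"):
            fit_sync((0.0, 600.0), (0.0, None))
        with pytest.raises(ValueError, match="pressure"):
            fit_sync(None, (0.0, 600.0))

    def test_corrected_click_alignment_below_2ms(self, wt_audio_recording,
                                                 wt_audio_result):
        _, _, truth = wt_audio_recording
        det = np.array([c.time for c in wt_audio_result.clicks])
        tru = np.sort(truth.clicks.time_s.to_numpy())
        near = np.abs(det[:, None] - tru[None, :]).min(axis=1)
        matched = near[near < 0.01]
        assert matched.size > 0
        assert matched.max() < 0.002

    def test_trigger_and_knock_found_on_both_channels(self, wt_audio_recording):
        trace, audio, truth = wt_audio_recording
        assert na.find_trigger(trace.samples, trace.sample_rate) == \
            pytest.approx(truth.trigger_s, abs=2e-3)
        assert na.find_knock(trace.samples, trace.sample_rate) == \
            pytest.approx(truth.knock_s, abs=2e-3)
        drift = 1 + 50e-6
        assert na.find_trigger(audio.samples, audio.sample_rate) == \
            pytest.approx(truth.trigger_s * drift, abs=1e-3)


class TestPeriEventHistogram:
    def test_clicks_at_event_times_fill_central_bin(self):
        ev = np.arange(10.0)
        h = peri_event_histogram(ev, ev, window_s=1.0, bin_s=0.02)
        assert h.mode_fraction == 1.0
        assert h.counts[h.central_bin] == 10
        assert h.counts.sum() == 10

    def test_alternating_15ms_offsets_split_adjacent_bins(self):
        ev = np.arange(20.0)
        clicks = ev + np.where(np.arange(20) % 2 == 0, 0.015, -0.015)
        h = peri_event_histogram(clicks, ev, window_s=1.0, bin_s=0.02)
        c = h.central_bin
        assert h.counts[c] == 0
        assert h.counts[c - 1] == 10 and h.counts[c + 1] == 10
        assert h.mode_fraction == 0.0

    def test_uniform_clicks_are_flat(self):
        rng = np.random.default_rng(2)
        ev = np.array([100.0])
        clicks = 100.0 + rng.uniform(-0.5, 0.5, 5000)
        h = peri_event_histogram(clicks, ev, window_s=1.0, bin_s=0.02)
        expect = h.counts.sum() / len(h.counts)
        assert np.all(np.abs(h.counts - expect) < 5 * np.sqrt(expect))

    def test_conservation(self):
        rng = np.random.default_rng(3)
        ev = rng.uniform(10, 90, 30)
        clicks = rng.uniform(0, 100, 400)
        h = peri_event_histogram(clicks, ev, window_s=2.0, bin_s=0.02)
        half = (len(h.counts) * 0.02) / 2
        inside = sum(((clicks - e >= -half) & (clicks - e < half)).sum()
                     for e in ev)
        assert h.counts.sum() == inside

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            peri_event_histogram([1.0], [], 1.0, 0.02)

    def test_uneven_bin_rejected(self):
        with pytest.raises(ValueError):
            peri_event_histogram([1.0], [1.0], 1.0, 0.03)


class TestContextFractions:
    def test_all_clicks_in_breath_holds(self):
        ctx = {"vocal": [(0, 1)], "breath_hold": [(2, 4)],
               "eupnea": [(5, 6)], "central": [(7, 8)]}
        cf = na.click_context_fractions([2.5, 3.0, 3.9], ctx)
        assert cf.fractions == {"vocal": 0.0, "breath_hold": 1.0,
                                "eupnea": 0.0, "central": 0.0}

    def test_fractions_sum_to_one(self):
        ctx = {"a": [(0, 1)], "b": [(1, 2)]}
        cf = na.click_context_fractions([0.5, 1.5, 1.7], ctx)
        assert sum(cf.fractions.values()) == pytest.approx(1.0)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            na.click_context_fractions([0.5], {"a": [(0, 2)], "b": [(1, 3)]})

    def test_zero_clicks_flagged_undefined(self):
        cf = na.click_context_fractions([], {"a": [(0, 1)]})
        assert cf.undefined
        assert np.isnan(cf.fractions["a"])
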