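"""Volume calibration, cycle detection and ventilation variables."""

from dataclasses import replace

import numpy as np
import pytest

import neoapnea as na
from neoapnea.segmentation import CalibrationError, PressureTrace

from conftest import make_series


def _step_trace(steps, fs=1000.0, duration=10.0, noise=0.001, seed=0):
    """Flat trace with upward steps of the given sizes at 2 s, 5 s, ..."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, noise, int(duration * fs))
    times = 2.0 + 3.0 * np.arange(len(steps))
    level = 0.0
    for t, s in zip(times, steps):
        level += s
        x[int(t * fs):] += s
    return PressureTrace(samples=x, sample_rate=fs), times


class TestCalibration:
    def test_single_injection_ratio(self):
        trace, times = _step_trace([0.5])
        assert na.calibrate_volume(trace, times) == pytest.approx(5.0, rel=1e-2)
        assert trace.volume_scale == pytest.approx(5.0, rel=1e-2)

    def test_two_injections_average(self):
        trace, times = _step_trace([0.5, 0.52])
        assert na.calibrate_volume(trace, times) == pytest.approx(
            2.5 / 0.51, rel=1e-2)

    def test_default_volume_is_2p5_uL(self):
        import inspect
        sig = inspect.signature(na.calibrate_volume)
        assert sig.parameters["injected_volume"].default == 2.5

    def test_missing_step_raises(self):
        trace, _ = _step_trace([0.5])
        with pytest.raises(CalibrationError):
            na.calibrate_volume(trace, [8.0])

    def test_scale_equivariance(self):
        trace, times = _step_trace([0.5])
        scaled = PressureTrace(samples=trace.samples * 4.0,
                               sample_rate=trace.sample_rate)
        s1 = na.calibrate_volume(trace, times)
        s2 = na.calibrate_volume(scaled, times)
        assert s2 == pytest.approx(s1 / 4.0, rel=1e-6)


class TestSegmentation:
    def _match(self, series, truth, window):
        det = series.onsets
        det = det[(det >= window[0] + 0.3) & (det <= window[1] - 0.3)]
        tru = truth.cycles
        inside = tru[(tru.onset_s >= window[0] + 0.3)
                     & (tru.onset_s + tru.duration_s <= window[1] - 0.3)]
        d = np.abs(det[:, None] - inside.onset_s.to_numpy()[None, :])
        recall = (d.min(axis=0) < 0.05).mean()
        precision = (d.min(axis=1) < 0.05).mean()
        return recall, precision, inside

    def test_noise_free_recall_precision_is_one(self, clean_profile):
        trace, _, truth = na.simulate_recording(clean_profile, 60, seed=2,
                                                with_audio=False)
        s = na.segment_breaths(trace, t_start=1.0, t_end=59.0)
        recall, precision, _ = self._match(s, truth, (1.0, 59.0))
        assert recall == 1.0 and precision == 1.0

    def test_noise_free_duration_accuracy(self, clean_profile):
        trace, _, truth = na.simulate_recording(clean_profile, 60, seed=2,
                                                with_audio=False)
        s = na.segment_breaths(trace, t_start=1.0, t_end=59.0)
        tru = truth.cycles.onset_s.to_numpy()
        tru_d = truth.cycles.duration_s.to_numpy()
        errs = []
        for o, d in zip(s.onsets, s.durations):
            j = np.argmin(np.abs(tru - o))
            if abs(tru[j] - o) < 0.05:
                errs.append(abs(tru_d[j] - d))
        errs = np.array(errs)
        # detector timing: median within 2 samples at 1 kHz, small tail
        assert np.median(errs) <= 0.002
        assert np.percentile(errs, 95) <= 0.006

    def test_noisy_recall_precision(self, clean_profile):
        p = replace(clean_profile, noise_sd=0.05)
        trace, _, truth = na.simulate_recording(p, 60, seed=2, with_audio=False)
        s = na.segment_breaths(trace, t_start=1.0, t_end=59.0)
        recall, precision, _ = self._match(s, truth, (1.0, 59.0))
        assert recall >= 0.98 and precision >= 0.98

    def test_central_pause_absorbed_into_te(self, clean_profile):
        p = replace(clean_profile, p_cl=0.05, dur_cl=(2.0, 2.5))
        trace, _, truth = na.simulate_recording(p, 60, seed=4, with_audio=False)
        s = na.segment_breaths(trace, t_start=1.0, t_end=59.0)
        pauses = truth.cycles[truth.cycles.kind == "central_like"]
        assert len(pauses) > 0
        for _, row in pauses.iterrows():
            if row.onset_s < 1.5 or row.onset_s + row.duration_s > 58.5:
                continue
            j = np.argmin(np.abs(s.onsets - row.onset_s))
            cyc = s.cycle(j)
            assert cyc.duration == pytest.approx(row.duration_s, abs=0.05)
            assert cyc.te > 0.8 * row.duration_s  # pause lives in Te

    def test_all_zero_trace_yields_empty_series(self):
        trace = PressureTrace(samples=np.zeros(5000), sample_rate=1000.0)
        with pytest.warns(UserWarning):
            s = na.segment_breaths(trace)
        assert len(s) == 0

    def test_cycles_fit_inside_the_window(self, mutant_recording):
        trace, _, _ = mutant_recording
        s = na.segment_breaths(trace, t_start=1.0, t_end=299.0)
        assert s.durations.sum() <= s.total_duration + 1e-6


class TestVentilation:
    def test_formula_arithmetic(self):
        s = make_series([0.4] * 10)
        v = na.ventilation_summary(s)
        assert v.fr_bpm == pytest.approx(150.0)
        assert v.vt == pytest.approx(8.0)
        assert v.ve == pytest.approx(150.0 * 8.0 / 1000.0)

    def test_weight_normalization_exposed(self):
        s = make_series([0.4] * 10)
        v = na.ventilation_summary(s, weight_g=1.5)
        assert v.ve_per_g == pytest.approx(v.ve / 1.5)

    def test_single_cycle_summary(self):
        s = make_series([0.5])
        v = na.ventilation_summary(s)
        assert v.fr_bpm == pytest.approx(120.0)

    def test_empty_series_rejected(self):
        s = make_series([0.4])
        s.cycles = s.cycles.iloc[0:0]
        with pytest.raises(ValueError):
            na.ventilation_summary(s)
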