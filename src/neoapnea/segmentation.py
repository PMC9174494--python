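"""Respiratory-cycle detection on whole-body plethysmography traces.

The chamber-pressure signal (inspiration upward, nominally sampled at
1 kHz) is low-pass filtered, referenced to a running end-expiratory
baseline, and split into cycles at inspiration onsets found with a
hysteresis detector.  Each cycle carries its inspiratory (Ti) and
expiratory (Te) durations, inspiratory amplitude and end-expiratory level;
apneic pauses are absorbed into the enclosing cycle's Te so that cycle
durations are the quantity classified downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PressureTrace",
    "BreathCycle",
    "CycleSeries",
    "CalibrationError",
    "calibrate_volume",
    "segment_breaths",
    "ventilation_summary",
    "VentilationSummary",
]

#: corner frequency of the cycle-detection low-pass filter (Hz)
LOWPASS_HZ = 20.0
#: wider-band corner used only to refine onset times once detected (Hz)
REFINE_LOWPASS_HZ = 60.0
#: onset refinement threshold, as a fraction of the running amplitude
REFINE_LEVEL = 0.04
#: running-baseline window (s) and percentile; the window is longer than the
#: longest apnea so a breath-hold plateau cannot capture the baseline
BASELINE_WINDOW_S = 8.0
BASELINE_PERCENTILE = 10.0
#: hysteresis thresholds for onset detection, as fractions of the running
#: inspiratory amplitude: arm below `LO`, fire above `HI`
HYST_LO = 0.05
HYST_HI = 0.15
#: cycles with amplitude above this multiple of the running tidal amplitude
#: are movement artifacts and are excluded
ARTIFACT_AMPLITUDE_FACTOR = 5.0


class CalibrationError(RuntimeError):
    """No detectable volume-injection step at a stated time."""


@dataclass
class PressureTrace:
    """Chamber-pressure samples with acquisition and calibration metadata.

    ``samples`` are raw transducer units unless ``volume_scale`` (uL per raw
    unit) is set, in which case ``samples * volume_scale`` are microliters.
    """

    samples: np.ndarray
    sample_rate: float
    trigger_time: float | None = None
    knock_time: float | None = None
    volume_scale: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("pressure samples must be finite")
        if self.trigger_time is not None and not (
                0 <= self.trigger_time <= self.duration):
            raise ValueError("trigger_time must lie within the record")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class BreathCycle:
    """One respiratory cycle; ``duration == ti + te`` exactly."""

    onset: float
    ti: float
    te: float
    amplitude: float
    end_exp_level: float

    @property
    def duration(self) -> float:
        return self.ti + self.te


@dataclass
class CycleSeries:
    """Time-ordered, non-overlapping respiratory cycles of one recording.

    ``cycles`` columns: onset_s, ti_s, te_s, duration_s, amplitude,
    end_exp.  ``total_duration`` is the analyzed span (s); the ratio of
    apneic cycle time to ``total_duration`` is the apneic time fraction.
    """

    cycles: pd.DataFrame
    total_duration: float

    def __post_init__(self) -> None:
        c = self.cycles
        if len(c):
            ends = c["onset_s"].to_numpy() + c["duration_s"].to_numpy()
            if np.any(np.diff(c["onset_s"].to_numpy()) <= 0):
                raise ValueError("cycles must be strictly time-ordered")
            if np.any(ends[:-1] > c["onset_s"].to_numpy()[1:] + 1e-9):
                raise ValueError("cycles must not overlap")

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def durations(self) -> np.ndarray:
        return self.cycles["duration_s"].to_numpy()

    @property
    def onsets(self) -> np.ndarray:
        return self.cycles["onset_s"].to_numpy()

    def cycle(self, i: int) -> BreathCycle:
        row = self.cycles.iloc[i]
        return BreathCycle(onset=row["onset_s"], ti=row["ti_s"], te=row["te_s"],
                           amplitude=row["amplitude"], end_exp_level=row["end_exp"])

    def to_csv(self, path) -> None:
        self.cycles.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, total_duration: float | None = None) -> "CycleSeries":
        df = pd.read_csv(path)
        if total_duration is None:
            last = df.iloc[-1]
            total_duration = float(last["onset_s"] + last["duration_s"]
                                   - df.iloc[0]["onset_s"])
        return cls(cycles=df, total_duration=total_duration)


# ---------------------------------------------------------------------------
# calibration

def calibrate_volume(trace: PressureTrace, injection_times,
                     injected_volume: float = 2.5) -> float:
    """Volume calibration from syringe air injections.

    Each injection of ``injected_volume`` uL (default 2.5) produces a step
    in chamber pressure; the scale is the injected volume divided by the
    mean step amplitude.  The scale is stored on the trace.
    """
    injection_times = np.atleast_1d(np.asarray(injection_times, dtype=float))
    if injection_times.size == 0:
        raise ValueError("at least one injection time is required")
    fs = trace.sample_rate
    x = trace.samples
    steps = []
    for t in injection_times:
        i = int(round(t * fs))
        pre = x[max(i - int(0.3 * fs), 0):max(i - int(0.02 * fs), 1)]
        post = x[i + int(0.02 * fs):i + int(0.3 * fs)]
        if pre.size == 0 or post.size == 0:
            raise CalibrationError(f"injection at {t:.3f} s is too close to an edge")
        step = float(np.median(post) - np.median(pre))
        noise = float(np.std(pre)) + 1e-12
        if step <= 3 * noise:
            raise CalibrationError(
                f"no detectable pressure step at {t:.3f} s (step {step:.4g}, "
                f"pre-injection SD {noise:.4g})")
        steps.append(step)
    scale = injected_volume / float(np.mean(steps))
    trace.volume_scale = scale
    return scale


# ---------------------------------------------------------------------------
# segmentation internals

def running_baseline(x: np.ndarray, fs: float,
                     window_s: float = BASELINE_WINDOW_S,
                     percentile: float = BASELINE_PERCENTILE) -> np.ndarray:
    """Running low-percentile baseline, evaluated on a coarse grid.

    A low percentile over a window longer than the longest apnea tracks the
    end-expiratory level while ignoring breath-hold plateaus.
    """
    n = x.size
    win = int(round(window_s * fs))
    if n <= win:
        return np.full(n, np.percentile(x, percentile))
    step = max(int(round(0.25 * fs)), 1)
    centers = np.arange(win // 2, n - win // 2, step)
    vals = np.empty(centers.size)
    for k, c in enumerate(centers):
        vals[k] = np.percentile(x[c - win // 2:c + win // 2], percentile)
    return np.interp(np.arange(n), centers, vals)


def _lowpass(x: np.ndarray, fs: float, fc: float = LOWPASS_HZ) -> np.ndarray:
    sos = signal.butter(4, fc / (fs / 2), btype="low", output="sos")
    return signal.sosfiltfilt(sos, x)


def _detect_onsets(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of inspiration onsets via hysteresis on the detrended signal.

    The detector arms when the signal falls below ``lo`` and fires at the
    next excursion above ``hi``; the reported onset is the last sample at or
    below ``lo`` before the firing sample (the upward ``lo``-crossing).
    """
    state = np.zeros(x.size, dtype=np.int8)
    state[x > hi] = 1
    state[x < lo] = -1
    idx = np.arange(x.size)
    # forward-fill the +-1 states
    filled_idx = np.where(state != 0, idx, 0)
    filled_idx = np.maximum.accumulate(filled_idx)
    filled = state[filled_idx]
    fire = np.flatnonzero((filled[1:] == 1) & (filled[:-1] == -1)) + 1
    if fire.size == 0:
        return fire
    # refine each firing sample back to the lo-crossing
    below = x <= lo
    last_below = np.where(below, idx, -1)
    last_below = np.maximum.accumulate(last_below)
    onsets = last_below[fire]
    return onsets[onsets >= 0]


def _refine_onsets(onsets: np.ndarray, x_wide: np.ndarray, fs: float,
                   thr: float) -> np.ndarray:
    """Sharpen onset samples on a wider-band signal.

    For each coarse onset the last upward crossing of ``thr`` within a
    +-30 ms neighborhood on ``x_wide`` is taken (the low-pass used for
    detection smears the inspiratory corner by several ms).
    """
    half = int(0.03 * fs)
    refined = onsets.astype(float).copy()
    for k, a in enumerate(onsets):
        w = x_wide[max(a - half, 0):min(a + half, x_wide.size)]
        if w.size < 3:
            continue
        above = w > thr
        cross = np.flatnonzero(~above[:-1] & above[1:])
        if cross.size == 0:
            continue
        j = cross[-1]
        # linear sub-sample interpolation of the threshold crossing
        frac = (thr - w[j]) / (w[j + 1] - w[j]) if w[j + 1] != w[j] else 0.0
        refined[k] = max(a - half, 0) + j + frac
    return refined


def segment_breaths(trace: PressureTrace, t_start: float | None = None,
                    t_end: float | None = None,
                    exclude_artifacts: bool = True) -> CycleSeries:
    """Detect respiratory cycles on ``trace`` within ``[t_start, t_end]``.

    Returns an empty series (with a warning) when no cycles are found, e.g.
    on a flat trace.  Amplitudes are microliters when the trace carries a
    volume scale, raw units otherwise.
    """
    fs = trace.sample_rate
    if trace.duration < 2.0:
        raise ValueError("need at least 2 s of signal")
    i0 = 0 if t_start is None else max(int(round(t_start * fs)), 0)
    i1 = trace.samples.size if t_end is None else min(
        int(round(t_end * fs)), trace.samples.size)
    raw = trace.samples[i0:i1]
    scale = trace.volume_scale if trace.volume_scale is not None else 1.0
    total_duration = raw.size / fs

    lp = _lowpass(raw, fs)
    base = running_baseline(lp, fs)
    x = lp - base
    amp = float(np.percentile(x, 99))
    if amp <= 0 or np.ptp(raw) == 0:
        warnings.warn("no respiratory signal detected; returning empty series")
        return CycleSeries(cycles=_empty_cycles(), total_duration=total_duration)

    onsets = _detect_onsets(x, HYST_LO * amp, HYST_HI * amp)
    if onsets.size < 2:
        warnings.warn("fewer than two inspiration onsets; returning empty series")
        return CycleSeries(cycles=_empty_cycles(), total_duration=total_duration)

    x_wide = _lowpass(raw, fs, REFINE_LOWPASS_HZ) - base
    refined = _refine_onsets(onsets, x_wide, fs, REFINE_LEVEL * amp)

    raw_detr = raw - base
    rows = []
    for (a, b), (ra, rb) in zip(zip(onsets[:-1], onsets[1:]),
                                zip(refined[:-1], refined[1:])):
        seg = x_wide[a:b]
        peak = a + int(np.argmax(seg))
        ti = (peak - ra) / fs
        dur = (rb - ra) / fs
        if ti <= 0 or dur - ti <= 0:
            continue
        rows.append((
            (i0 + ra) / fs,              # onset_s, trace clock
            ti,
            dur - ti,
            dur,
            float(raw_detr[peak]) * scale,
            float(raw_detr[max(b - 1, a)]) * scale,
        ))
    df = pd.DataFrame(rows, columns=["onset_s", "ti_s", "te_s", "duration_s",
                                     "amplitude", "end_exp"])
    if exclude_artifacts and len(df):
        med_amp = float(np.median(df["amplitude"]))
        bad = df["amplitude"] > ARTIFACT_AMPLITUDE_FACTOR * med_amp
        total_duration -= float(df.loc[bad, "duration_s"].sum())
        df = df.loc[~bad].reset_index(drop=True)
    return CycleSeries(cycles=df, total_duration=total_duration)


def _empty_cycles() -> pd.DataFrame:
    return pd.DataFrame(columns=["onset_s", "ti_s", "te_s", "duration_s",
                                 "amplitude", "end_exp"])


# ---------------------------------------------------------------------------
# ventilation variables

@dataclass(frozen=True)
class VentilationSummary:
    """Breathing frequency, tidal volume and minute ventilation.

    ``fr_bpm`` is the mean of per-cycle 60/(Ti+Te); ``vt`` the mean
    inspiratory amplitude (uL); ``ve = fr * vt / 1000``; ``ve_per_g`` is the
    same divided by body weight when a weight was supplied.
    """

    fr_bpm: float
    vt: float
    ve: float
    ve_per_g: float | None


def ventilation_summary(series: CycleSeries,
                        weight_g: float | None = None) -> VentilationSummary:
    if len(series) == 0:
        raise ValueError("cannot summarize an empty cycle series")
    fr = float(np.mean(60.0 / series.durations))
    vt = float(np.mean(series.cycles["amplitude"]))
    ve = fr * vt / 1000.0
    return VentilationSummary(
        fr_bpm=fr, vt=vt, ve=ve,
        ve_per_g=ve / weight_g if weight_g else None)
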