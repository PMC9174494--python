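"""Click detection, audio/pressure clock synchronization and peri-event
statistics for joint ultrasound-audio + plethysmography recordings.

Clicks are sub-millisecond broad-band transients associated with the
re-opening of closed airway cavities.  They are detected as short-time
energy excursions of the high-pass-filtered audio, kept only when brief
(< 2 ms) and spectrally flat (which rejects tonal ultrasonic
vocalizations).  Because the audio and pressure acquisition clocks drift
relative to each other (crystal rating +-50 ppm, i.e. >= 10 ms/min), a
two-point linear map fitted on a shared start-of-record trigger pulse and
an end-of-record chamber knock brings detected click times onto the
pressure clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "AudioTrace",
    "ClickEvent",
    "SyncModel",
    "detect_clicks",
    "find_trigger",
    "find_knock",
    "fit_sync",
    "peri_event_histogram",
    "PeriEventHistogram",
    "click_context_fractions",
    "ContextFractions",
]

MIN_AUDIO_RATE = 20_000.0
HIGHPASS_HZ = 5_000.0
FRAME_S = 0.00025          # short-time energy frame
ENERGY_K_MAD = 8.0         # threshold: median + k * MAD of frame energy
MAX_CLICK_S = 0.002
#: events shorter than this are single-frame noise excursions, not clicks
MIN_CLICK_S = 0.0004
REFRACTORY_S = 0.010
FLATNESS_MIN = 0.4


@dataclass
class AudioTrace:
    """Mono audio samples (float) with their sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class ClickEvent:
    """A detected click: onset time (s, channel clock), duration (s) and
    peak-band energy in dB over the local noise floor."""

    time: float
    duration: float
    energy_db: float


def _spectral_flatness(x: np.ndarray, fs: float, f_lo: float) -> float:
    """Spectral flatness (geometric / arithmetic mean of the power
    spectrum) restricted to the analysis passband above ``f_lo``."""
    p = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    p = p[freqs >= f_lo]
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def detect_clicks(audio: AudioTrace,
                  highpass_hz: float = HIGHPASS_HZ,
                  k_mad: float = ENERGY_K_MAD,
                  max_duration_s: float = MAX_CLICK_S,
                  min_duration_s: float = MIN_CLICK_S,
                  refractory_s: float = REFRACTORY_S,
                  flatness_min: float = FLATNESS_MIN,
                  exclude_windows=None) -> list[ClickEvent]:
    """Detect clicks in ``audio`` (channel clock times).

    Candidates are frames of high-pass-filtered short-time energy exceeding
    ``median + k_mad * MAD``; frames closer than the refractory period are
    merged into one event, events longer than ``max_duration_s`` (knocks,
    trigger pulses, vocalization bouts) or spectrally tonal (flatness below
    ``flatness_min``) are discarded.  ``exclude_windows`` is an optional
    list of (start, end) times to ignore (e.g. around sync marks).

    Silent or empty audio returns an empty list.
    """
    fs = audio.sample_rate
    if fs < MIN_AUDIO_RATE:
        raise ValueError(f"audio sample rate must be >= {MIN_AUDIO_RATE} Hz")
    x = np.asarray(audio.samples, dtype=np.float64)
    if x.size == 0 or np.ptp(x) == 0:
        return []
    sos = signal.butter(4, highpass_hz / (fs / 2), btype="high", output="sos")
    y = signal.sosfilt(sos, x)

    frame_n = max(int(FRAME_S * fs), 4)
    n_frames = y.size // frame_n
    if n_frames < 8:
        return []
    energy = np.square(y[:n_frames * frame_n].reshape(n_frames, frame_n)).sum(axis=1)
    med = np.median(energy)
    mad = np.median(np.abs(energy - med)) + 1e-30
    thresh = med + k_mad * 1.4826 * mad
    hot = np.flatnonzero(energy > thresh)
    if hot.size == 0:
        return []

    # group frames separated by less than the refractory period
    refr_frames = max(int(refractory_s / FRAME_S), 1)
    splits = np.flatnonzero(np.diff(hot) > refr_frames) + 1
    groups = np.split(hot, splits)

    events: list[ClickEvent] = []
    for g in groups:
        start = g[0] * frame_n
        end = (g[-1] + 1) * frame_n
        dur = (end - start) / fs
        if dur >= max_duration_s or dur < min_duration_s:
            continue
        t = start / fs
        if exclude_windows and any(a <= t <= b for a, b in exclude_windows):
            continue
        pad = int(0.001 * fs)
        snippet = y[max(start - pad, 0):end + pad]
        if _spectral_flatness(snippet, fs, 1.2 * highpass_hz) < flatness_min:
            continue
        peak = float(energy[g].max())
        events.append(ClickEvent(
            time=t, duration=dur,
            energy_db=10.0 * np.log10(peak / (med + 1e-30))))
    return events


# ---------------------------------------------------------------------------
# synchronization marks

def _mark_onset(x: np.ndarray, fs: float, channel: str) -> int:
    """Onset sample of the most prominent sustained pulse in ``x``.

    The candidate is the peak of a 2 ms rectified moving average (which
    suppresses sub-millisecond clicks relative to the >= 5 ms sync marks);
    the onset is the first sample near the candidate whose rectified,
    median-removed amplitude crosses half the local peak.
    """
    ax = np.abs(x - np.median(x))
    win = max(int(0.002 * fs), 3)
    kernel = np.ones(win) / win
    env = np.convolve(ax, kernel, mode="same")
    c = int(np.argmax(env))
    w0 = max(c - int(0.015 * fs), 0)
    w1 = min(c + int(0.015 * fs), len(ax))
    local = ax[w0:w1]
    thresh = 0.5 * float(local.max())
    hits = np.flatnonzero(local >= thresh)
    if hits.size == 0:
        raise ValueError(f"no sync mark found in the {channel} channel")
    return w0 + int(hits[0])


def find_trigger(samples: np.ndarray, sample_rate: float,
                 search_s: float = 5.0, channel: str = "") -> float:
    """Time of the shared start-of-record trigger pulse (rising edge),
    searched in the first ``search_s`` seconds of the channel."""
    n = min(int(search_s * sample_rate), len(samples))
    if n < 10:
        raise ValueError("record too short to contain a trigger")
    x = np.asarray(samples[:n], dtype=float)
    return _mark_onset(x, sample_rate, channel or "trigger-search") / sample_rate


def find_knock(samples: np.ndarray, sample_rate: float,
               tail_fraction: float = 0.10, channel: str = "") -> float:
    """Time of the end-of-record chamber knock: onset of the largest
    sustained impulse in the final ``tail_fraction`` of the record."""
    x = np.asarray(samples, dtype=float)
    start = int(len(x) * (1.0 - tail_fraction))
    if len(x) - start < 10:
        raise ValueError("record too short to contain a knock")
    i = _mark_onset(x[start:], sample_rate, channel or "knock-search")
    return (start + i) / sample_rate


@dataclass(frozen=True)
class SyncModel:
    """Two-point linear map from the audio clock to the pressure clock.

    ``audio_t = slope * pressure_t + intercept``; ``drift_ppm`` is
    ``(slope - 1) * 1e6``.  ``residual`` is the mark-detection jitter
    propagated to a worst-case alignment error (s).
    """

    slope: float
    intercept: float
    residual: float

    @property
    def offset(self) -> float:
        return self.intercept

    @property
    def drift_ppm(self) -> float:
        return (self.slope - 1.0) * 1e6

    def audio_to_pressure(self, t):
        return (np.asarray(t, dtype=float) - self.intercept) / self.slope

    def pressure_to_audio(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept


def fit_sync(pressure_marks: tuple[float, float],
             audio_marks: tuple[float, float],
             pressure_jitter_s: float = 1e-3,
             audio_jitter_s: float = 2.5e-4) -> SyncModel:
    """Fit the audio-to-pressure clock map from trigger and knock marks.

    ``pressure_marks`` and ``audio_marks`` are (trigger_time, knock_time)
    in each channel's own clock.  Raises if a mark is missing or the marks
    are degenerate, naming the offending channel.
    """
    for name, marks in (("pressure", pressure_marks), ("audio", audio_marks)):
        if marks is None or len(marks) != 2 or any(m is None for m in marks):
            raise ValueError(f"missing trigger/knock mark in the {name} channel")
    (tp, kp), (ta, ka) = pressure_marks, audio_marks
    if kp <= tp:
        raise ValueError("pressure knock must follow the trigger")
    slope = (ka - ta) / (kp - tp)
    if abs((slope - 1.0) * 1e6) > 200:
        raise ValueError(f"implausible clock drift: {(slope - 1) * 1e6:.0f} ppm")
    intercept = ta - slope * tp
    jitter = float(np.hypot(pressure_jitter_s, audio_jitter_s))
    # worst case inside the record: mark error at one anchor plus the
    # drift-estimate error accumulated back over the full span
    residual = 2.0 * jitter
    return SyncModel(slope=slope, intercept=intercept, residual=residual)


# ---------------------------------------------------------------------------
# peri-event statistics

@dataclass
class PeriEventHistogram:
    """Binned click offsets around alignment events.

    The central bin spans [-bin/2, +bin/2); ``mode_fraction`` is the
    fraction of events whose nearest click falls in the central bin.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mode_fraction: float
    n_events: int

    @property
    def central_bin(self) -> int:
        return len(self.counts) // 2


def peri_event_histogram(click_times, event_times, window_s: float = 1.0,
                         bin_s: float = 0.02) -> PeriEventHistogram:
    """Histogram of click offsets within ``+-window_s/2`` of each event.

    ``bin_s`` must evenly divide ``window_s``; an odd number of bins is
    used so that one bin is centered on zero (ties fall in the earlier
    bin).
    """
    click_times = np.sort(np.asarray(click_times, dtype=float))
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("event list is empty")
    ratio = window_s / bin_s
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("bin_s must evenly divide window_s")
    n_bins = int(round(ratio))
    if n_bins % 2 == 0:
        n_bins += 1
    edges = (np.arange(n_bins + 1) - n_bins / 2.0) * bin_s
    half = n_bins * bin_s / 2.0

    offsets = []
    central_hits = 0
    for ev in event_times:
        rel = click_times - ev
        inside = rel[(rel >= -half) & (rel < half)]
        offsets.append(inside)
        if inside.size:
            nearest = inside[np.argmin(np.abs(inside))]
            if -bin_s / 2.0 <= nearest < bin_s / 2.0:
                central_hits += 1
    all_off = np.concatenate(offsets) if offsets else np.array([])
    counts, _ = np.histogram(all_off, bins=edges)
    return PeriEventHistogram(bin_edges=edges, counts=counts,
                              mode_fraction=central_hits / event_times.size,
                              n_events=int(event_times.size))


# ---------------------------------------------------------------------------
# click context attribution

@dataclass
class ContextFractions:
    """Fraction of clicks per breathing context; NaN-filled and flagged when
    no click could be assigned."""

    fractions: dict
    counts: dict
    n_assigned: int
    n_clicks: int
    undefined: bool


def click_context_fractions(click_times, contexts: dict) -> ContextFractions:
    """Assign each click to the breathing context containing it.

    ``contexts`` maps labels (e.g. vocal / breath_hold / eupnea / central)
    to lists of (start, end) intervals on the pressure clock.  Intervals
    must not overlap across labels; clicks outside every interval are left
    unassigned.  Fractions are over assigned clicks and sum to 1 when at
    least one click is assigned.
    """
    click_times = np.asarray(click_times, dtype=float)
    flat = []
    for label, intervals in contexts.items():
        for (a, b) in intervals:
            if b <= a:
                raise ValueError(f"empty interval in context {label!r}")
            flat.append((a, b, label))
    flat.sort()
    for (a1, b1, l1), (a2, b2, l2) in zip(flat[:-1], flat[1:]):
        if a2 < b1 - 1e-9:
            raise ValueError(
                f"overlapping context intervals: {l1} [{a1}, {b1}) and "
                f"{l2} [{a2}, {b2})")
    starts = np.array([f[0] for f in flat])
    ends = np.array([f[1] for f in flat])
    labels = [f[2] for f in flat]

    counts = {label: 0 for label in contexts}
    n_assigned = 0
    for t in click_times:
        i = np.searchsorted(starts, t, side="right") - 1
        if i >= 0 and t < ends[i]:
            counts[labels[i]] += 1
            n_assigned += 1
    if n_assigned == 0:
        fractions = {label: float("nan") for label in contexts}
        return ContextFractions(fractions=fractions, counts=counts,
                                n_assigned=0, n_clicks=click_times.size,
                                undefined=True)
    fractions = {label: c / n_assigned for label, c in counts.items()}
    return ContextFractions(fractions=fractions, counts=counts,
                            n_assigned=n_assigned, n_clicks=click_times.size,
                            undefined=False)
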