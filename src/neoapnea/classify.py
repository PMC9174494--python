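"""Typing of apneic cycles: breath-holding vs central-like.

A breath-holding apnea starts post-inspiration with partial or complete
retention of the inspired air (a pressure plateau above the end-expiratory
baseline), may carry resuming inspiratory efforts of growing amplitude,
and is often terminated by an abrupt deflation with a time-locked click.
A central-like apnea is a pause at baseline following a normal breath
(lung deflated).

Classification is by the median pause-window pressure level in tidal-volume
units: ``breath_hold`` at or above ``PLATEAU_THETA`` (or above the deflated
ceiling with a click time-locked to the terminal deflation); ``central_like``
below the deflated ceiling.  Intermediate levels without a click are
ambiguous and resolved to ``central_like`` (the conservative tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .apnea import ApneaSummary
from .audio import ClickEvent
from .segmentation import CycleSeries, PressureTrace, _lowpass, running_baseline

__all__ = ["ApneaEvent", "classify_apnea", "classify_apneas", "atf_by_type",
           "PLATEAU_THETA", "DEFLATED_CEILING", "CLICK_WINDOW_S"]

#: plateau threshold for breath holding, in V_T units
PLATEAU_THETA = 0.3
#: pause levels below this (in V_T) mean the lung is deflated
DEFLATED_CEILING = 0.1
#: click-association window around the terminal deflation (s)
CLICK_WINDOW_S = 0.1


@dataclass
class ApneaEvent:
    """One typed apneic cycle."""

    cycle_index: int
    onset: float
    duration: float
    kind: str                       # breath_hold | central_like
    plateau_level: float            # median pause level in V_T units
    has_resuming_efforts: bool
    click_time: float | None
    ambiguous: bool

    def __post_init__(self) -> None:
        if self.kind not in ("breath_hold", "central_like"):
            raise ValueError(f"unknown apnea type {self.kind!r}")
        if not -0.5 <= self.plateau_level <= 1.5:
            raise ValueError("plateau_level outside [-0.5, 1.5]")


def _reference_vt(series: CycleSeries) -> float:
    """Tidal amplitude of the repetitive population (median amplitude of
    cycles at most twice the median duration)."""
    c = series.cycles
    med = float(np.median(c["duration_s"]))
    rep = c[c["duration_s"] <= 2.0 * med]
    pool = rep if len(rep) else c
    return float(np.median(pool["amplitude"]))


def classify_apneas(trace: PressureTrace, series: CycleSeries,
                    apneic_indices, clicks: list[ClickEvent] | None = None,
                    theta: float = PLATEAU_THETA,
                    deflated: float = DEFLATED_CEILING,
                    click_window_s: float = CLICK_WINDOW_S) -> list[ApneaEvent]:
    """Classify each apneic cycle in ``apneic_indices``.

    ``clicks`` carry pressure-clock times (already synchronized).  The
    trace is detrended once and shared across events.
    """
    fs = trace.sample_rate
    scale = trace.volume_scale if trace.volume_scale is not None else 1.0
    lp = _lowpass(trace.samples, fs)
    x = (lp - running_baseline(lp, fs)) * scale
    vt = _reference_vt(series)
    med_dur = float(np.median(series.durations))
    click_times = np.sort([c.time for c in clicks]) if clicks else np.array([])

    events = []
    for idx in np.atleast_1d(np.asarray(apneic_indices, dtype=int)):
        events.append(_classify_one(x, fs, series, int(idx), vt, med_dur,
                                    click_times, theta, deflated,
                                    click_window_s))
    return events


def classify_apnea(trace: PressureTrace, series: CycleSeries,
                   apneic_index: int,
                   clicks: list[ClickEvent] | None = None,
                   **kwargs) -> ApneaEvent:
    """Classify a single apneic cycle (see :func:`classify_apneas`)."""
    return classify_apneas(trace, series, [apneic_index], clicks, **kwargs)[0]


def _classify_one(x: np.ndarray, fs: float, series: CycleSeries, idx: int,
                  vt: float, med_dur: float, click_times: np.ndarray,
                  theta: float, deflated: float,
                  click_window_s: float) -> ApneaEvent:
    if not 0 <= idx < len(series):
        raise IndexError(f"apneic cycle index {idx} out of range")
    row = series.cycles.iloc[idx]
    onset, dur = float(row["onset_s"]), float(row["duration_s"])
    i0 = int(round(onset * fs))
    i1 = int(round((onset + dur) * fs))

    # the pause: skip one median cycle length (the leading breath) and the
    # terminal 150 ms (deflation)
    p0 = i0 + int(med_dur * fs)
    p1 = i1 - int(0.15 * fs)
    if p1 <= p0:
        p0, p1 = i0 + (i1 - i0) // 2, i1
    pause = x[p0:p1]
    level = float(np.clip(np.median(pause) / vt, -0.5, 1.5))

    # terminal deflation: the final fall below the deflated level (the
    # pause-terminating collapse to baseline before the next onset)
    tail = x[p0:i1]
    thr = max(deflated, 0.5 * level) * vt
    above = np.flatnonzero(tail >= thr)
    if above.size:
        t_defl = (p0 + above[-1] + 1) / fs
    else:
        t_defl = onset + dur
    click_time = None
    if click_times.size:
        j = int(np.argmin(np.abs(click_times - t_defl)))
        if abs(click_times[j] - t_defl) <= click_window_s:
            click_time = float(click_times[j])

    # resuming efforts: >= 2 inspiratory deflections of increasing
    # amplitude riding on the plateau
    efforts = False
    if pause.size > int(0.5 * fs):
        peaks, props = _signal.find_peaks(
            pause, prominence=0.08 * vt, distance=int(0.15 * fs))
        prom = props.get("prominences", np.array([]))
        efforts = peaks.size >= 2 and bool(np.all(np.diff(prom) > -0.02 * vt))

    ambiguous = False
    if level >= theta:
        kind = "breath_hold"
    elif level >= deflated and click_time is not None:
        kind = "breath_hold"
    elif level < deflated:
        kind = "central_like"
    else:
        kind = "central_like"
        ambiguous = True
    return ApneaEvent(cycle_index=idx, onset=onset, duration=dur, kind=kind,
                      plateau_level=level, has_resuming_efforts=efforts,
                      click_time=click_time, ambiguous=ambiguous)


def atf_by_type(summary: ApneaSummary, events: list[ApneaEvent],
                total_duration: float) -> ApneaSummary:
    """Split the total ATF into breath-holding and central-like components.

    The partition is exact: ``atf_bh + atf_cl == atf``.  Raises when the
    events do not cover exactly the apneic cycles of the summary.
    """
    if len(events) != summary.n_apneas:
        raise ValueError(
            f"{len(events)} typed events do not cover {summary.n_apneas} "
            "apneic cycles")
    atf_bh = sum(e.duration for e in events if e.kind == "breath_hold") \
        / total_duration
    summary.atf_bh = float(min(atf_bh, summary.atf))
    summary.atf_cl = summary.atf - summary.atf_bh
    return summary
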