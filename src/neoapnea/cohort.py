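"""Per-recording analysis pipeline, cohort tables and group comparisons.

``analyze_recording`` chains the full pipeline on one pup: sync-mark
detection, breath segmentation, CORC estimation, apnea labeling, typing
(plateau rule, click-assisted when audio is available) and the ventilation
summary.  ``per_pup_metrics`` aggregates recordings into a cohort table
(one row per pup).  ``compare_groups`` applies the normality-gated test
selection used throughout: Student's t when both samples pass a normality
test at alpha = 0.05 (Shapiro-Wilk below n = 20, D'Agostino-Pearson
otherwise), Mann-Whitney / Wilcoxon when not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import audio as audio_mod
from .apnea import ApneaSummary, apnea_summary, corc_logthd, corc_poincare, label_cycles
from .audio import AudioTrace, SyncModel, detect_clicks, find_knock, find_trigger, fit_sync
from .classify import ApneaEvent, atf_by_type, classify_apneas
from .segmentation import CycleSeries, PressureTrace, segment_breaths, ventilation_summary

__all__ = ["RecordingResult", "TestResult", "analyze_recording",
           "per_pup_metrics", "compare_groups", "percent_change"]

log = logging.getLogger(__name__)

#: margins trimmed around the sync marks before segmentation (s)
EDGE_AFTER_TRIGGER_S = 0.5
EDGE_BEFORE_KNOCK_S = 0.3
NORMALITY_ALPHA = 0.05
SHAPIRO_MAX_N = 20


@dataclass
class RecordingResult:
    """Everything the pipeline derived from one recording."""

    series: CycleSeries
    summary: ApneaSummary
    events: list[ApneaEvent]
    clicks: list
    sync: SyncModel | None
    ventilation: object
    metadata: dict = field(default_factory=dict)

    def row(self) -> dict:
        return {
            "pup_id": self.metadata.get("pup_id"),
            "profile": self.metadata.get("profile"),
            "atf": self.summary.atf,
            "atf_bh": self.summary.atf_bh,
            "atf_cl": self.summary.atf_cl,
            "n_apneas": self.summary.n_apneas,
            "corc_s": self.summary.corc,
            "fr_bpm": self.ventilation.fr_bpm,
            "vt_uL": self.ventilation.vt,
            "ve": self.ventilation.ve,
            "n_clicks": len(self.clicks),
        }


def analyze_recording(trace: PressureTrace, audio: AudioTrace | None = None,
                      corc_method: str = "poincare") -> RecordingResult:
    """Run the full apnea-phenotyping pipeline on one recording.

    With audio, clicks are detected, brought onto the pressure clock via
    the trigger/knock two-point map, and used for click-assisted typing;
    without audio the typing falls back to the plateau rule alone.
    """
    fs = trace.sample_rate
    trig = trace.trigger_time
    knock = trace.knock_time
    try:
        if trig is None:
            trig = find_trigger(trace.samples, fs)
        if knock is None:
            knock = find_knock(trace.samples, fs)
    except ValueError:
        trig = trig or 0.0
        knock = knock or trace.duration

    series = segment_breaths(trace, t_start=trig + EDGE_AFTER_TRIGGER_S,
                             t_end=knock - EDGE_BEFORE_KNOCK_S)

    clicks: list = []
    sync = None
    if audio is not None:
        p_trig = find_trigger(trace.samples, fs)
        p_knock = find_knock(trace.samples, fs)
        a_trig = find_trigger(audio.samples, audio.sample_rate)
        a_knock = find_knock(audio.samples, audio.sample_rate)
        sync = fit_sync((p_trig, p_knock), (a_trig, a_knock),
                        pressure_jitter_s=1.0 / fs,
                        audio_jitter_s=1.0 / audio.sample_rate)
        guard = 0.05
        raw_clicks = detect_clicks(audio, exclude_windows=[
            (a_trig - guard, a_trig + 0.02 + guard),
            (a_knock - guard, a_knock + 0.02 + guard)])
        clicks = [
            audio_mod.ClickEvent(
                time=float(sync.audio_to_pressure(c.time)),
                duration=c.duration, energy_db=c.energy_db)
            for c in raw_clicks]

    corc = corc_poincare(series) if corc_method == "poincare" \
        else corc_logthd(series)
    summary = apnea_summary(series, corc)
    apneic_idx = np.flatnonzero(label_cycles(series, corc) == "apneic")
    events = classify_apneas(trace, series, apneic_idx, clicks=clicks)
    summary = atf_by_type(summary, events, series.total_duration)
    vent = ventilation_summary(series, trace.metadata.get("weight_g"))
    return RecordingResult(series=series, summary=summary, events=events,
                           clicks=clicks, sync=sync, ventilation=vent,
                           metadata=dict(trace.metadata))


def per_pup_metrics(recordings, corc_method: str = "poincare") -> pd.DataFrame:
    """Cohort table: one row per recording.

    ``recordings`` is an iterable of ``(PressureTrace, AudioTrace | None)``
    pairs or of ``(trace, audio, truth)`` triples as returned by the
    simulator.  A failing recording is logged and skipped; the pipeline
    continues.
    """
    rows = []
    for rec in recordings:
        trace, audio = rec[0], (rec[1] if len(rec) > 1 else None)
        try:
            result = analyze_recording(trace, audio, corc_method=corc_method)
            rows.append(result.row())
        except Exception as exc:  # row-level failure, keep going
            log.warning("recording %s failed: %s",
                        getattr(trace, "metadata", {}).get("pup_id", "?"), exc)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics

@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group comparison, recording the path taken."""

    test: str
    statistic: float
    p_value: float
    n: tuple
    paired: bool
    normal: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _is_normal(x: np.ndarray) -> bool:
    if np.ptp(x) == 0:
        return False
    if len(x) < SHAPIRO_MAX_N:
        p = stats.shapiro(x).pvalue
    else:
        p = stats.normaltest(x).pvalue
    return p > NORMALITY_ALPHA


def compare_groups(x, y, paired: bool = False) -> TestResult:
    """Normality-gated two-group comparison.

    Both samples normal -> Student's t (paired or unpaired); otherwise
    Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired and len(x) != len(y):
        raise ValueError("paired samples must have matching lengths")
    if paired and np.allclose(x, y):
        return TestResult(test="paired t (degenerate: zero differences)",
                          statistic=0.0, p_value=1.0, n=(len(x), len(y)),
                          paired=True, normal=True)
    normal = _is_normal(x) and _is_normal(y)
    if normal:
        if paired:
            res = stats.ttest_rel(x, y)
            name = "paired t"
        else:
            res = stats.ttest_ind(x, y)
            name = "unpaired t"
    else:
        if paired:
            res = stats.wilcoxon(x, y)
            name = "Wilcoxon"
        else:
            res = stats.mannwhitneyu(x, y)
            name = "Mann-Whitney"
    return TestResult(test=name, statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(len(x), len(y)),
                      paired=paired, normal=normal)


def percent_change(pre, post) -> float:
    """Percent change of the mean, ``100 * (mean(post) - mean(pre)) /
    mean(pre)``; raises when the pre mean is zero."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    m = pre.mean()
    if m == 0:
        raise ZeroDivisionError("percent change undefined: pre-mean is zero")
    return float(100.0 * (post.mean() - m) / m)
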