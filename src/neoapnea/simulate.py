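"""Synthetic neonatal-mouse plethysmography and joint ultrasound audio.

Generates paired pressure/audio recordings with complete ground truth for a
:class:`~neoapnea.profiles.SimProfile`.  The pressure channel (1 kHz,
inspiration upward) is a concatenation of cycles drawn from the profile's
stationary mixture:

* regular cycle - quarter-sine inspiration over Ti, exponential return
  over Te;
* breath-holding apnea - normal inspiration, then a plateau at
  ``plateau_frac * V_T`` (optionally carrying resuming inspiratory efforts
  of growing amplitude), terminated by a small upward pressure shift and a
  rapid deflation; a click is emitted at the shift with ``p_click_bh``;
* central-like apnea - a normal breath followed by a pause at baseline;
* vocal cycle - a regular cycle with an expiratory lung compression, a
  surrogate ultrasonic-vocalization tone and a click at the compression
  re-opening with ``p_click_vocal``.

Apneas are isolated by construction: after an apneic cycle the next cycle
is forced regular, and the post-regular apnea probabilities are inflated to
``p / (1 - p_bh - p_cl)`` so the stationary per-cycle apnea fractions still
equal the profile's nominal probabilities (this keeps the simulated apneic
time fraction unbiased with respect to ``expected_summary``).

Both channels carry a 10 ms trigger pulse near the start and a coincident
knock impulse near the end; the audio channel's clock is remapped by
``drift_ppm`` relative to the pressure clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .audio import AudioTrace
from .profiles import MIN_CYCLE_S, VOCAL_BOUT_CYCLES, SimProfile
from .segmentation import PressureTrace

__all__ = ["GroundTruth", "simulate_recording", "simulate_cohort",
           "PRESSURE_FS", "AUDIO_FS"]

PRESSURE_FS = 1000.0   # Hz
AUDIO_FS = 50_000.0    # Hz; analysis accepts any rate >= 20 kHz

TRIGGER_TIME_S = 0.2
TRIGGER_WIDTH_S = 0.010
KNOCK_FROM_END_S = 0.5
#: time between the terminal upward pressure shift and the end of a
#: breath-hold cycle (shift + rapid deflation)
BH_TERMINAL_S = 0.13
#: probability that a breath hold carries resuming inspiratory efforts
P_RESUMING_EFFORTS = 0.7

CLICK_DUR_S = 0.0005
CLICK_AMP = 0.4
USV_FREQ_HZ = 17_000.0
USV_AMP = 0.25
AUDIO_NOISE_SD = 0.003
KNOCK_AUDIO_AMP = 0.95
TRIGGER_AUDIO_AMP = 0.5


@dataclass
class GroundTruth:
    """Programmed truth for one simulated recording.

    ``cycles`` columns: onset_s, duration_s, kind (regular / breath_hold /
    central_like / vocal), click_s (NaN when no click).  ``clicks`` columns:
    time_s (pressure clock), context.  ATFs are fractions of the
    cycle-covered time.
    """

    cycles: pd.DataFrame
    clicks: pd.DataFrame
    trigger_s: float
    knock_s: float
    atf_by_type: dict = field(default_factory=dict)

    @property
    def atf_total(self) -> float:
        return self.atf_by_type.get("breath_hold", 0.0) + \
            self.atf_by_type.get("central_like", 0.0)

    def cycle_count(self, t0: float | None = None, t1: float | None = None,
                    kind: str | None = None) -> int:
        c = self.cycles
        if kind is not None:
            c = c[c["kind"] == kind]
        if t0 is not None:
            c = c[c["onset_s"] >= t0]
        if t1 is not None:
            c = c[c["onset_s"] + c["duration_s"] <= t1]
        return len(c)


# ---------------------------------------------------------------------------
# cycle-sequence sampling

def _draw_cycles(profile: SimProfile, duration_s: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Sample the (kind, duration, amplitude) sequence tiling the record."""
    p_bh, p_cl = profile.p_bh, profile.p_cl
    q = 1.0 - p_bh - p_cl
    # post-regular probabilities preserving the stationary kind fractions
    a_bh, a_cl = p_bh / q, p_cl / q
    if profile.sigma_reg > 0:
        tn = stats.truncnorm((MIN_CYCLE_S - profile.mu_reg) / profile.sigma_reg,
                             np.inf, loc=profile.mu_reg, scale=profile.sigma_reg)
    else:
        tn = None

    kinds, durs, amps = [], [], []
    t = 0.0
    prev_apneic = False
    while True:
        if prev_apneic:
            kind = "regular"
        else:
            u = rng.random()
            kind = ("breath_hold" if u < a_bh
                    else "central_like" if u < a_bh + a_cl else "regular")
        if kind == "regular":
            d = float(tn.rvs(random_state=rng)) if tn is not None else profile.mu_reg
        elif kind == "breath_hold":
            d = float(rng.uniform(*profile.dur_bh))
        else:
            d = float(rng.uniform(*profile.dur_cl))
        if t + d > duration_s:
            break
        amp = float(profile.vt_mean * max(rng.normal(1.0, 0.1), 0.3))
        kinds.append(kind)
        durs.append(d)
        amps.append(amp)
        t += d
        prev_apneic = kind != "regular"
    onsets = np.concatenate([[0.0], np.cumsum(durs)[:-1]]) if durs else np.array([])
    return pd.DataFrame({"onset_s": onsets, "duration_s": durs,
                         "kind": kinds, "amplitude": amps})


def _mark_vocal_bouts(cycles: pd.DataFrame, profile: SimProfile,
                      duration_s: float, rng: np.random.Generator) -> None:
    """Convert runs of regular cycles into vocal bouts, in place."""
    if profile.vocal_rate <= 0 or len(cycles) == 0:
        return
    n_bouts = rng.poisson(profile.vocal_rate * duration_s / 60.0)
    kinds = cycles["kind"].to_numpy().copy()
    n = len(kinds)
    for _ in range(n_bouts):
        # a bout needs VOCAL_BOUT_CYCLES consecutive regular cycles
        for _attempt in range(20):
            i = int(rng.integers(0, max(n - VOCAL_BOUT_CYCLES, 1)))
            run = kinds[i:i + VOCAL_BOUT_CYCLES]
            if len(run) == VOCAL_BOUT_CYCLES and np.all(run == "regular"):
                kinds[i:i + VOCAL_BOUT_CYCLES] = "vocal"
                break
    cycles["kind"] = kinds


# ---------------------------------------------------------------------------
# waveform synthesis

def _regular_wave(n: int, ti_n: int, amp: float) -> np.ndarray:
    w = np.zeros(n)
    ti_n = min(max(ti_n, 1), n - 1)
    w[:ti_n] = amp * np.sin(0.5 * np.pi * np.arange(ti_n) / ti_n)
    te_n = n - ti_n
    tau = max(te_n / 4.0, 1.0)
    w[ti_n:] = amp * np.exp(-np.arange(te_n) / tau)
    return w


def _vocal_wave(n: int, ti_n: int, amp: float, fs: float) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Regular cycle with an expiratory compression dip.

    Returns (waveform, compression re-opening time within the cycle,
    USV interval within the cycle).
    """
    w = _regular_wave(n, ti_n, amp)
    te_n = n - ti_n
    tc = ti_n + int(0.45 * te_n)
    width = max(int(0.015 * fs), 2)
    idx = np.arange(n)
    w -= 0.35 * amp * np.exp(-0.5 * ((idx - tc) / width) ** 2)
    # the call is emitted during the compression; the re-opening click
    # follows the end of the tone burst
    t_open = (tc + 2 * width) / fs
    usv = ((tc - 4 * width) / fs, (tc + 0.5 * width) / fs)
    return w, t_open, usv


def _breath_hold_wave(n: int, amp: float, profile: SimProfile, fs: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Breath-hold cycle; returns (waveform, terminal-shift time in cycle)."""
    ti_n = max(int(profile.ti_fraction * profile.mu_reg * fs), 2)
    plateau = profile.plateau_frac * amp
    term_n = int(BH_TERMINAL_S * fs)
    shift_i = n - term_n
    w = np.empty(n)
    ti_n = min(ti_n, shift_i - 1)
    w[:ti_n] = amp * np.sin(0.5 * np.pi * np.arange(ti_n) / ti_n)
    # settle from the inspiratory peak onto the plateau
    k = np.arange(shift_i - ti_n)
    w[ti_n:shift_i] = plateau + (amp - plateau) * np.exp(-k / (0.05 * fs))
    # resuming inspiratory efforts of progressively increasing amplitude
    span_n = shift_i - ti_n - int(0.2 * fs)
    if span_n > int(1.0 * fs) and rng.random() < P_RESUMING_EFFORTS:
        n_eff = min(max(int(span_n / fs / 0.35), 2), 6)
        starts = ti_n + int(0.2 * fs) + (
            np.linspace(0, span_n - int(0.3 * fs), n_eff)).astype(int)
        heights = np.linspace(0.2, 1.0, n_eff) * (amp - plateau)
        rise = max(int(0.08 * fs), 2)
        fall = max(int(0.12 * fs), 2)
        bump = np.concatenate([
            np.sin(0.5 * np.pi * np.arange(rise) / rise),
            np.exp(-np.arange(fall) / (fall / 3.0))])
        for s, h in zip(starts, heights):
            e = min(s + bump.size, shift_i)
            w[s:e] += h * bump[:e - s]
    # terminal upward shift then rapid deflation
    shift_n = max(int(0.02 * fs), 2)
    level = w[shift_i - 1]
    seg = min(shift_n, n - shift_i)
    w[shift_i:shift_i + seg] = level + 0.15 * amp * \
        np.sin(0.5 * np.pi * np.arange(seg) / seg)
    k = np.arange(n - shift_i - seg)
    w[shift_i + seg:] = (level + 0.15 * amp) * np.exp(-k / (0.025 * fs))
    return w, shift_i / fs


def _central_wave(n: int, amp: float, profile: SimProfile,
                  fs: float) -> np.ndarray:
    """A normal breath followed by a deflated pause filling the cycle."""
    breath_n = min(int(profile.mu_reg * fs), n)
    ti_n = max(int(profile.ti_fraction * profile.mu_reg * fs), 2)
    w = np.zeros(n)
    w[:breath_n] = _regular_wave(breath_n, ti_n, amp)
    return w


# ---------------------------------------------------------------------------
# recording assembly

def simulate_recording(profile: SimProfile, duration_s: float, seed,
                       with_audio: bool = True
                       ) -> tuple[PressureTrace, AudioTrace | None, GroundTruth]:
    """Simulate one pup recording.

    ``seed`` may be an int or a sequence of ints (fed to numpy's seeding
    machinery); identical arguments give bit-identical outputs.  When
    ``with_audio`` is false the audio channel is skipped (pressure-only
    analyses) and ``None`` is returned in its place.
    """
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10 to place trigger and knock")
    rng = np.random.default_rng(seed)
    fs = PRESSURE_FS

    cycles = _draw_cycles(profile, duration_s, rng)
    _mark_vocal_bouts(cycles, profile, duration_s, rng)

    n_samples = int(round(duration_s * fs))
    pressure = np.zeros(n_samples)
    click_rows: list[tuple[float, str]] = []
    usv_intervals: list[tuple[float, float]] = []
    cycle_click = np.full(len(cycles), np.nan)

    for i, row in enumerate(cycles.itertuples(index=False)):
        i0 = int(round(row.onset_s * fs))
        n = int(round((row.onset_s + row.duration_s) * fs)) - i0
        if n <= 3:
            continue
        if row.kind == "regular":
            ti_n = max(int(profile.ti_fraction * n), 2)
            pressure[i0:i0 + n] = _regular_wave(n, ti_n, row.amplitude)
            if rng.random() < profile.p_click_eup:
                t_click = row.onset_s + 0.002
                click_rows.append((t_click, "eupnea"))
        elif row.kind == "vocal":
            ti_n = max(int(profile.ti_fraction * n), 2)
            w, t_open, usv = _vocal_wave(n, ti_n, row.amplitude, fs)
            pressure[i0:i0 + n] = w
            usv_intervals.append((row.onset_s + usv[0], row.onset_s + usv[1]))
            if rng.random() < profile.p_click_vocal:
                t_click = row.onset_s + t_open
                click_rows.append((t_click, "vocal"))
                cycle_click[i] = t_click
        elif row.kind == "breath_hold":
            w, t_shift = _breath_hold_wave(n, row.amplitude, profile, fs, rng)
            pressure[i0:i0 + n] = w
            if rng.random() < profile.p_click_bh:
                t_click = row.onset_s + t_shift
                click_rows.append((t_click, "breath_hold"))
                cycle_click[i] = t_click
        else:  # central_like
            pressure[i0:i0 + n] = _central_wave(n, row.amplitude, profile, fs)
            if rng.random() < profile.p_click_cl:
                t_click = row.onset_s + profile.mu_reg + \
                    0.5 * (row.duration_s - profile.mu_reg)
                click_rows.append((t_click, "central"))
                cycle_click[i] = t_click

    cycles = cycles.copy()
    cycles["click_s"] = cycle_click

    # sensor noise
    if profile.noise_sd > 0:
        pressure += rng.normal(0.0, profile.noise_sd * profile.vt_mean,
                               size=n_samples)

    # trigger pulse and end-of-record knock, both channels
    trig_i = int(TRIGGER_TIME_S * fs)
    trig_n = int(TRIGGER_WIDTH_S * fs)
    pressure[trig_i:trig_i + trig_n] += 2.0 * profile.vt_mean
    knock_s = duration_s - KNOCK_FROM_END_S
    knock_i = int(knock_s * fs)
    k = np.arange(int(0.02 * fs))
    pressure[knock_i:knock_i + k.size] += \
        3.0 * profile.vt_mean * np.exp(-k / (0.003 * fs))

    trace = PressureTrace(
        samples=pressure, sample_rate=fs, trigger_time=TRIGGER_TIME_S,
        knock_time=knock_s, volume_scale=1.0,
        metadata={"profile": profile.name, "weight_g": profile.weight_g})

    clicks = pd.DataFrame(click_rows, columns=["time_s", "context"])

    covered = float(cycles["duration_s"].sum())
    atf_by_type = {
        kind: float(cycles.loc[cycles["kind"] == kind, "duration_s"].sum())
        / covered
        for kind in ("breath_hold", "central_like")
    } if covered > 0 else {}
    truth = GroundTruth(cycles=cycles, clicks=clicks,
                        trigger_s=TRIGGER_TIME_S, knock_s=knock_s,
                        atf_by_type=atf_by_type)

    audio = _render_audio(profile, duration_s, clicks, usv_intervals,
                          knock_s, rng) if with_audio else None
    return trace, audio, truth


def _render_audio(profile: SimProfile, duration_s: float,
                  clicks: pd.DataFrame, usv_intervals, knock_s: float,
                  rng: np.random.Generator) -> AudioTrace:
    drift = 1.0 + profile.drift_ppm * 1e-6
    fs = AUDIO_FS
    n = int(round(duration_s * drift * fs))
    audio = rng.normal(0.0, AUDIO_NOISE_SD, size=n).astype(np.float32)

    def sample(t_pressure: float) -> int:
        return int(round(t_pressure * drift * fs))

    # trigger: 10 ms rectangular pulse
    i = sample(TRIGGER_TIME_S)
    audio[i:i + int(TRIGGER_WIDTH_S * fs)] += TRIGGER_AUDIO_AMP
    # knock: 5 ms loud broadband burst
    i = sample(knock_s)
    kn = int(0.005 * fs)
    audio[i:i + kn] += (KNOCK_AUDIO_AMP *
                        rng.standard_normal(kn).astype(np.float32))
    # clicks: 0.5 ms broadband bursts
    cn = max(int(CLICK_DUR_S * fs), 8)
    for t in clicks["time_s"]:
        i = sample(float(t))
        if i + cn < n:
            audio[i:i + cn] += (CLICK_AMP *
                                rng.standard_normal(cn).astype(np.float32))
    # USV surrogates: tone bursts in the 15-20 kHz band
    for t0, t1 in usv_intervals:
        i0, i1 = sample(t0), sample(t1)
        if i1 <= i0 or i1 >= n:
            continue
        tt = np.arange(i1 - i0) / fs
        tone = USV_AMP * np.sin(2 * np.pi * USV_FREQ_HZ * tt)
        ramp = min(int(0.002 * fs), (i1 - i0) // 2)
        if ramp > 0:
            tone[:ramp] *= np.linspace(0, 1, ramp)
            tone[-ramp:] *= np.linspace(1, 0, ramp)
        audio[i0:i1] += tone.astype(np.float32)
    return AudioTrace(samples=audio, sample_rate=fs)


def simulate_cohort(profile: SimProfile, n_pups: int, duration_s: float,
                    seed: int, with_audio: bool = True):
    """Simulate ``n_pups`` independent recordings.

    Per-pup seeds are the counter pairs ``[seed, pup_index]``, so cohorts
    are reproducible and each pup's recording can be regenerated alone with
    ``simulate_recording(profile, duration_s, [seed, i])``.

    Returns ``(recordings, truth_table)`` where ``recordings`` is a list of
    ``(PressureTrace, AudioTrace | None, GroundTruth)`` and ``truth_table``
    has one row per pup with the programmed ATFs.
    """
    if n_pups < 1:
        raise ValueError("n_pups must be >= 1")
    recordings = []
    rows = []
    for i in range(n_pups):
        trace, audio, truth = simulate_recording(
            profile, duration_s, seed=[seed, i], with_audio=with_audio)
        trace.metadata["pup_id"] = f"{profile.name}_p{i:02d}"
        recordings.append((trace, audio, truth))
        rows.append({
            "pup_id": trace.metadata["pup_id"],
            "profile": profile.name,
            "atf_bh": truth.atf_by_type.get("breath_hold", 0.0),
            "atf_cl": truth.atf_by_type.get("central_like", 0.0),
            "atf_total": truth.atf_total,
            "n_clicks": len(truth.clicks),
        })
    return recordings, pd.DataFrame(rows)
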