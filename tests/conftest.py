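"""Shared fixtures: synthetic series builders and cached simulated pups."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import neoapnea as na
from neoapnea.segmentation import CycleSeries


def make_series(durations, total_duration=None, amplitude=8.0) -> CycleSeries:
    """Build a CycleSeries directly from a list of cycle durations."""
    durations = np.asarray(durations, dtype=float)
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    df = pd.DataFrame({
        "onset_s": onsets,
        "ti_s": 0.35 * durations,
        "te_s": 0.65 * durations,
        "duration_s": durations,
        "amplitude": amplitude,
        "end_exp": 0.0,
    })
    return CycleSeries(cycles=df, total_duration=float(
        durations.sum() if total_duration is None else total_duration))


def bimodal_durations(rng, n=800, p_apnea=0.05, mu=0.4, sd=0.02,
                      apnea_range=(2.0, 5.0)):
    """Isolated-apnea mixture of short repetitive and long apneic cycles."""
    apneic = rng.random(n) < p_apnea
    d = rng.normal(mu, sd, n)
    d[apneic] = rng.uniform(*apnea_range, apneic.sum())
    for i in range(1, n):  # enforce isolation
        if apneic[i] and apneic[i - 1]:
            d[i] = rng.normal(mu, sd)
            apneic[i] = False
    return np.abs(d), apneic


@pytest.fixture(scope="session")
def clean_profile():
    """Noise-free, apnea-free, non-vocal regular breathing."""
    return replace(na.build_profile("control_P0_12h"), name="clean",
                   noise_sd=0.0, p_bh=0.0, p_cl=0.0, vocal_rate=0.0,
                   p_click_eup=0.0, p_click_cl=0.0)


@pytest.fixture(scope="session")
def mutant_recording():
    """One 300 s mutant pup (pressure only), simulated once per session."""
    profile = na.build_profile("mutant_n4A_P0_12h")
    return na.simulate_recording(profile, 300, seed=42, with_audio=False)


@pytest.fixture(scope="session")
def wt_audio_recording():
    """One 300 s wild-type pup with joint ultrasound audio."""
    profile = na.build_profile("wt_joint_audio")
    return na.simulate_recording(profile, 300, seed=7, with_audio=True)


@pytest.fixture(scope="session")
def wt_audio_result(wt_audio_recording):
    trace, audio, _ = wt_audio_recording
    return na.analyze_recording(trace, audio)
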