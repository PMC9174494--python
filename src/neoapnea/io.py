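"""Reading and writing of traces, tables and profiles.

Pressure traces travel as mono float WAV or two-column CSV
(``time_s,pressure``); ultrasound audio as 16-bit WAV; cycle tables,
ground truth and click lists as CSV; profiles as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .audio import AudioTrace
from .profiles import SimProfile
from .segmentation import PressureTrace

__all__ = [
    "write_pressure_wav", "read_pressure_wav",
    "write_pressure_csv", "read_pressure_csv",
    "write_audio_wav", "read_audio_wav",
    "write_profile_yaml", "read_profile_yaml",
    "write_summary_json",
]


def write_pressure_wav(path, trace: PressureTrace) -> None:
    wavfile.write(path, int(trace.sample_rate),
                  trace.samples.astype(np.float32))


def read_pressure_wav(path, **metadata) -> PressureTrace:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    return PressureTrace(samples=np.asarray(data, dtype=float),
                         sample_rate=float(rate), metadata=metadata)


def write_pressure_csv(path, trace: PressureTrace) -> None:
    pd.DataFrame({"time_s": trace.times(),
                  "pressure": trace.samples}).to_csv(path, index=False)


def read_pressure_csv(path, **metadata) -> PressureTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("pressure CSV must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return PressureTrace(samples=df["pressure"].to_numpy(dtype=float),
                         sample_rate=fs, metadata=metadata)


def write_audio_wav(path, audio: AudioTrace) -> None:
    x = np.asarray(audio.samples, dtype=np.float64)
    peak = float(np.max(np.abs(x))) or 1.0
    scaled = np.clip(x / max(peak, 1.0), -1.0, 1.0)
    wavfile.write(path, int(audio.sample_rate),
                  (scaled * 32767).astype(np.int16))


def read_audio_wav(path) -> AudioTrace:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return AudioTrace(samples=data, sample_rate=float(rate))


def write_profile_yaml(path, profile: SimProfile) -> None:
    Path(path).write_text(yaml.safe_dump(profile.to_dict(), sort_keys=False))


def read_profile_yaml(path) -> SimProfile:
    return SimProfile.from_dict(yaml.safe_load(Path(path).read_text()))


def write_summary_json(path, summary: dict) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(summary, indent=2, default=_default))
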