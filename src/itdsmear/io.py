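"""WAV and configuration file handling."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from scipy.io import wavfile

from .stimulus import Waveform

__all__ = ["read_wav", "write_wav", "load_config", "dump_config"]


def read_wav(path) -> Waveform:
    """Read a PCM16/PCM32/float WAV into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit unsigned
        data = (data.astype(float) - 128.0) / 127.0
    else:
        data = data.astype(float)
    return Waveform(data, float(rate))


def write_wav(path, w: Waveform, subtype: str = "float32") -> None:
    """Write a waveform as float32 (default) or PCM16 WAV."""
    if subtype == "float32":
        wavfile.write(path, int(w.rate), w.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(w.samples, -1.0, 1.0)
        wavfile.write(path, int(w.rate), (clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype: {subtype!r}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
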