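"""Audio and table I/O helpers (RIFF WAV via scipy, CSV via pandas)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = ["read_wav", "write_wav", "read_annotations", "write_annotations"]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV as float in [-1, 1]; returns (waveform, sample_rate)."""
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return data, int(sr)


def write_wav(path, waveform: np.ndarray, sample_rate_hz: int) -> None:
    """Write a float waveform in [-1, 1] as 16-bit PCM mono WAV."""
    clipped = np.clip(np.asarray(waveform, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate_hz, (clipped * 32767).astype(np.int16))


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)
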