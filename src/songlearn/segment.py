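"""Syllable segmentation and frame-level spectral features.

A waveform is cut into short overlapping frames (default 9 ms, 1.5 ms step,
Hann window) and each frame is summarized by the standard song-analysis
features: amplitude, mean frequency (spectral centroid), Wiener entropy,
fundamental-frequency estimate with its goodness of pitch, and frequency
modulation. Syllables are maximal runs of frames whose amplitude exceeds a
threshold above the estimated noise floor, separated by silence gaps.

Numerical notes
---------------
* Wiener entropy is ``log(geometric mean / arithmetic mean)`` of the power
  spectrum (natural log, DC excluded), which is <= 0 and equals 0 for a
  flat spectrum. It is computed on a band-averaged spectrum (16-bin bands):
  raw periodogram bins of white noise are exponentially distributed and
  would bias the statistic to about -0.58 even for a perfectly flat
  spectrum; band-averaging brings the white-noise value to ~ -0.03.
  The spectrum is normalized first, so the statistic is exactly invariant
  to global amplitude scaling.
* Pitch is the parabolic-interpolated peak of the frame autocorrelation
  within a search band (default 300-3000 Hz); goodness of pitch is the
  normalized height of that peak. Frames whose goodness falls below a
  floor are marked unvoiced and carry a missing pitch value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["FrameConfig", "compute_frames", "segment_syllables"]

FRAME_FEATURES = [
    "time_s",
    "amplitude_db",
    "mean_frequency_hz",
    "wiener_entropy",
    "pitch_hz",
    "goodness_of_pitch",
    "frequency_modulation",
    "voiced",
]


class FrameConfig:
    """Frame-analysis parameters (defaults follow common song-analysis use)."""

    def __init__(
        self,
        frame_ms: float = 9.0,
        step_ms: float = 1.5,
        pitch_min_hz: float = 300.0,
        pitch_max_hz: float = 3000.0,
        goodness_floor: float = 0.25,
        wiener_bands: int = 16,
    ) -> None:
        self.frame_ms = frame_ms
        self.step_ms = step_ms
        self.pitch_min_hz = pitch_min_hz
        self.pitch_max_hz = pitch_max_hz
        self.goodness_floor = goodness_floor
        self.wiener_bands = wiener_bands


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def compute_frames(
    waveform: np.ndarray,
    sample_rate_hz: int,
    config: FrameConfig | None = None,
) -> pd.DataFrame:
    """Compute per-frame acoustic features for a mono waveform.

    Returns one row per frame with columns :data:`FRAME_FEATURES`;
    ``time_s`` is the frame onset. All-zero (silent) frames get a very low
    amplitude and are marked unvoiced rather than raising.
    """
    cfg = config or FrameConfig()
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("waveform must be a nonempty 1-D array")
    frame_len = int(round(cfg.frame_ms * sample_rate_hz / 1000.0))
    step = max(int(round(cfg.step_ms * sample_rate_hz / 1000.0)), 1)
    if frame_len < 2:
        raise ValueError("frame_ms must span at least 2 samples")
    if x.size < frame_len:
        x = np.pad(x, (0, frame_len - x.size))

    frames = sliding_window_view(x, frame_len)[::step]
    n_frames = frames.shape[0]
    window = np.hanning(frame_len)
    fw = frames * window

    # power spectrum, zero-padded to the next power of two, DC excluded
    nfft = _next_pow2(frame_len)
    spec = np.fft.rfft(fw, n=nfft, axis=1)
    power = np.abs(spec) ** 2
    power = power[:, 1:]
    freqs = np.fft.rfftfreq(nfft, d=1.0 / sample_rate_hz)[1:]

    total = power.sum(axis=1)
    silent = total <= 0
    safe_total = np.where(silent, 1.0, total)
    amplitude_db = 10.0 * np.log10(np.where(silent, 1e-20, total))
    centroid = (power * freqs).sum(axis=1) / safe_total
    centroid[silent] = np.nan

    # Wiener entropy on the normalized, band-averaged spectrum
    n_bins = power.shape[1]
    n_bands = max(cfg.wiener_bands, 1)
    band_edges = np.linspace(0, n_bins, n_bands + 1).astype(int)
    bands = np.stack([
        power[:, band_edges[i]:band_edges[i + 1]].mean(axis=1)
        for i in range(n_bands)
    ], axis=1)
    bands = bands / np.where(silent, 1.0, bands.sum(axis=1))[:, None]
    bands = np.maximum(bands, 1e-12)
    wiener = np.log(np.exp(np.mean(np.log(bands), axis=1)) / bands.mean(axis=1))
    wiener = np.minimum(wiener, 0.0)
    wiener[silent] = 0.0

    pitch, goodness = _autocorr_pitch(fw, sample_rate_hz, cfg)
    voiced = (goodness >= cfg.goodness_floor) & ~silent
    pitch = np.where(voiced, pitch, np.nan)

    fm = np.empty(n_frames)
    step_s = step / sample_rate_hz
    if n_frames > 1:
        d = np.abs(np.diff(centroid)) / step_s
        fm[1:] = d
        fm[0] = d[0] if d.size else 0.0
    else:
        fm[:] = 0.0

    out = pd.DataFrame({
        "time_s": np.arange(n_frames) * step_s,
        "amplitude_db": amplitude_db,
        "mean_frequency_hz": centroid,
        "wiener_entropy": wiener,
        "pitch_hz": pitch,
        "goodness_of_pitch": goodness,
        "frequency_modulation": fm,
        "voiced": voiced,
    })
    out.attrs["frame_ms"] = cfg.frame_ms
    return out


def _autocorr_pitch(
    fw: np.ndarray, sample_rate_hz: int, cfg: FrameConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Fundamental frequency + goodness via the frame autocorrelation peak."""
    n_frames, frame_len = fw.shape
    nfft = _next_pow2(2 * frame_len)
    spec = np.fft.rfft(fw, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, :frame_len]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = 1.0
    acn = ac / r0[:, None]

    lag_min = max(int(np.floor(sample_rate_hz / cfg.pitch_max_hz)), 2)
    lag_max = min(int(np.ceil(sample_rate_hz / cfg.pitch_min_hz)), frame_len - 2)
    if lag_max <= lag_min:
        return np.full(n_frames, np.nan), np.zeros(n_frames)

    band = acn[:, lag_min:lag_max + 1]
    best = np.argmax(band, axis=1) + lag_min
    goodness = np.clip(acn[np.arange(n_frames), best], 0.0, 1.0)

    # parabolic interpolation of the peak lag for sub-sample pitch accuracy
    lm = best.astype(float)
    interior = (best > lag_min) & (best < lag_max)
    i = np.where(interior)[0]
    if i.size:
        y0 = acn[i, best[i] - 1]
        y1 = acn[i, best[i]]
        y2 = acn[i, best[i] + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        lm[i] = best[i] + np.clip(shift, -1.0, 1.0)
    pitch = sample_rate_hz / lm
    return pitch, goodness


def segment_syllables(
    frames: pd.DataFrame,
    amplitude_threshold_db: float = 20.0,
    min_syllable_ms: float = 10.0,
    min_gap_ms: float = 10.0,
    noise_floor_db: float | None = None,
    frame_ms: float | None = None,
) -> pd.DataFrame:
    """Detect syllables as loud frame runs separated by silence gaps.

    The activity threshold is ``amplitude_threshold_db`` above the noise
    floor (10th percentile of frame amplitude unless given, so the floor
    tracks the silent gaps even when most of a clip is song). Gaps shorter than
    ``min_gap_ms`` are merged into the surrounding syllable; runs shorter
    than ``min_syllable_ms`` are discarded. Because a frame is active
    whenever its window overlaps any sound, boundaries are compensated for
    the frame span (``frame_ms``; taken from the frame table's metadata
    when not given): onset = first active frame start + frame length,
    offset = last active frame start + step. Returns a table with
    ``onset_s`` / ``offset_s``; empty for silent input.
    """
    if amplitude_threshold_db <= 0 or min_syllable_ms <= 0 or min_gap_ms <= 0:
        raise ValueError("thresholds must be positive")
    amp = frames["amplitude_db"].to_numpy()
    times = frames["time_s"].to_numpy()
    if len(frames) < 2:
        return pd.DataFrame(columns=["onset_s", "offset_s"])
    step_s = float(np.median(np.diff(times)))
    floor = float(np.percentile(amp, 10)) if noise_floor_db is None else noise_floor_db
    active = amp >= floor + amplitude_threshold_db
    if not active.any():
        return pd.DataFrame(columns=["onset_s", "offset_s"])

    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(np.flatnonzero(np.diff(np.r_[0, active.astype(int)]) == 1))
    ends = list(np.flatnonzero(np.diff(np.r_[active.astype(int), 0]) == -1))
    del edges

    # merge runs separated by gaps shorter than min_gap_ms
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and (times[s] - times[merged[-1][1]]) * 1000.0 < min_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    if frame_ms is None:
        frame_ms = float(frames.attrs.get("frame_ms", 9.0))
    frame_s = frame_ms / 1000.0
    rows = []
    for s, e in merged:
        onset = times[s] + frame_s - step_s / 2
        offset = times[e] + step_s / 2
        if offset <= onset:
            continue  # run shorter than the frame smear: below resolution
        if (offset - onset) * 1000.0 >= min_syllable_ms:
            rows.append({"onset_s": onset, "offset_s": offset})
    return pd.DataFrame(rows, columns=["onset_s", "offset_s"])
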