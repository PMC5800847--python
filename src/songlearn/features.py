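"""Per-syllable acoustic feature summaries and cFF detection.

Frame features are reduced to one record per syllable (arithmetic mean over
the frames inside the annotation), and harmonic-stack syllables are scanned
for a constant-fundamental-frequency (cFF) segment: a voiced frame run of
at least ``min_segment_ms`` whose pitch varies by at most
``ff_tolerance_rel`` (SD/mean). When several segments qualify, the one with
the lowest mean fundamental is reported, matching how the lowest flat
harmonic stack of a syllable is used for trial-by-trial pitch-variability
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SyllableFeatures", "summarize_syllable", "detect_cff", "feature_table"]

SUMMARY_FEATURES = [
    "mean_frequency_hz",
    "wiener_entropy",
    "goodness_of_pitch",
    "frequency_modulation",
]


@dataclass(frozen=True)
class SyllableFeatures:
    onset_s: float
    offset_s: float
    duration_ms: float
    mean_frequency_hz: float
    wiener_entropy: float
    goodness_of_pitch: float
    frequency_modulation: float
    pitch_hz: float  # median over voiced frames (robust to edge frames); NaN if none
    cff_hz: float | None = None
    cff_segment: tuple[float, float] | None = None


def _frames_inside(frames: pd.DataFrame, onset_s: float, offset_s: float) -> pd.DataFrame:
    t = frames["time_s"]
    return frames[(t >= onset_s) & (t < offset_s)]


def summarize_syllable(
    frames: pd.DataFrame, onset_s: float, offset_s: float
) -> SyllableFeatures:
    """Reduce the frames inside [onset, offset) to one feature record."""
    if offset_s <= onset_s:
        raise ValueError("offset must exceed onset")
    inside = _frames_inside(frames, onset_s, offset_s)
    if inside.empty:
        raise ValueError("no frames inside the syllable annotation")
    voiced_pitch = inside.loc[inside["voiced"], "pitch_hz"]
    return SyllableFeatures(
        onset_s=onset_s,
        offset_s=offset_s,
        duration_ms=(offset_s - onset_s) * 1000.0,
        mean_frequency_hz=float(inside["mean_frequency_hz"].mean()),
        wiener_entropy=float(inside["wiener_entropy"].mean()),
        goodness_of_pitch=float(inside["goodness_of_pitch"].mean()),
        frequency_modulation=float(inside["frequency_modulation"].mean()),
        pitch_hz=float(voiced_pitch.median()) if len(voiced_pitch) else float("nan"),
    )


def detect_cff(
    frames: pd.DataFrame,
    onset_s: float,
    offset_s: float,
    ff_tolerance_rel: float = 0.01,
    min_segment_ms: float = 30.0,
) -> tuple[float, tuple[float, float]] | None:
    """Find the lowest constant-fundamental segment of a syllable.

    Scans the voiced frames inside the annotation for maximal contiguous
    windows whose pitch SD/mean stays within ``ff_tolerance_rel`` and whose
    span is at least ``min_segment_ms``; returns ``(cff_hz, (start_s,
    end_s))`` for the qualifying segment with the lowest mean fundamental,
    or ``None`` when no segment qualifies (absence is a value, not an
    error). The tolerance rule is an automatic surrogate for the manual
    segment marking used with interactive song-analysis software.
    """
    if ff_tolerance_rel <= 0 or min_segment_ms <= 0:
        raise ValueError("tolerance and minimum segment length must be positive")
    inside = _frames_inside(frames, onset_s, offset_s).reset_index(drop=True)
    if inside.empty:
        return None
    voiced = inside["voiced"].to_numpy()
    pitch = inside["pitch_hz"].to_numpy()
    times = inside["time_s"].to_numpy()
    if len(times) > 1:
        step_s = float(np.median(np.diff(times)))
    else:
        step_s = 0.0

    # maximal voiced runs
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(inside)
    while i < n:
        if voiced[i] and np.isfinite(pitch[i]):
            j = i
            while j + 1 < n and voiced[j + 1] and np.isfinite(pitch[j + 1]):
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    candidates: list[tuple[float, float, float]] = []  # (mean_hz, start_s, end_s)
    for a, b in runs:
        prev_end = -1
        for s in range(a, b + 1):
            # grow the window from s while the flatness criterion holds
            e = s
            acc = pitch[s]
            acc2 = pitch[s] ** 2
            count = 1
            while e + 1 <= b:
                na = acc + pitch[e + 1]
                na2 = acc2 + pitch[e + 1] ** 2
                nc = count + 1
                mean = na / nc
                var = max(na2 / nc - mean**2, 0.0)
                if np.sqrt(var) / mean > ff_tolerance_rel:
                    break
                e += 1
                acc, acc2, count = na, na2, nc
            if e <= prev_end:
                continue  # contained in an earlier maximal window
            prev_end = e
            span_ms = (times[e] - times[s] + step_s) * 1000.0
            if span_ms >= min_segment_ms:
                candidates.append((acc / count, times[s], times[e] + step_s))

    if not candidates:
        return None
    mean_hz, start_s, end_s = min(candidates, key=lambda c: c[0])
    return float(mean_hz), (float(start_s), float(end_s))


def feature_table(
    frames: pd.DataFrame,
    annotations: pd.DataFrame,
    ff_tolerance_rel: float = 0.01,
    min_segment_ms: float = 30.0,
) -> pd.DataFrame:
    """Summarize every annotated syllable of one file into a tidy table.

    ``annotations`` needs ``onset_s``/``offset_s``; any other columns
    (label, bird_id, context, ...) are carried through.
    """
    rows = []
    for _, ann in annotations.iterrows():
        feats = summarize_syllable(frames, ann["onset_s"], ann["offset_s"])
        cff = detect_cff(frames, ann["onset_s"], ann["offset_s"],
                         ff_tolerance_rel, min_segment_ms)
        row = dict(ann)
        row.update({
            "duration_ms": feats.duration_ms,
            "mean_frequency_hz": feats.mean_frequency_hz,
            "wiener_entropy": feats.wiener_entropy,
            "goodness_of_pitch": feats.goodness_of_pitch,
            "frequency_modulation": feats.frequency_modulation,
            "pitch_hz": feats.pitch_hz,
            "cff_hz": cff[0] if cff else np.nan,
            "cff_start_s": cff[1][0] if cff else np.nan,
            "cff_end_s": cff[1][1] if cff else np.nan,
        })
        rows.append(row)
    return pd.DataFrame(rows)
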