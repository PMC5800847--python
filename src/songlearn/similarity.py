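"""Frame-based asymmetric motif similarity and syllable accuracy.

A pupil motif is scored against a tutor motif frame by frame: every
vocalized pupil frame looks for its nearest tutor frame (Euclidean
distance in z-scored feature space: mean frequency, Wiener entropy,
goodness of pitch, frequency modulation, pitch) within a sliding temporal
window, and the similarity score is the percentage of pupil frames whose
nearest distance falls under a threshold. The comparison is asymmetric —
pupil against tutor, never the reverse — so omitted or replaced pupil
content directly lowers the matched fraction.

The distance threshold is not arbitrary: it is calibrated as a low
quantile (default 5%) of nearest-frame distances between *unrelated*
synthetic songs, so frames from unrelated song content fail the threshold
by construction. This scoring is a documented surrogate for proprietary
song-similarity software; its absolute scale is its own and is not
comparable to scores printed by that software.

Aggregation follows the standard recipe: 20 pupil renditions x 10 tutor
renditions = 200 pairwise scores; the motif similarity is their mean and
the maximum similarity is the mean of the top 5% (``ceil(0.05 n)``, i.e.
exactly the 10 highest of 200).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "SIMILARITY_FEATURES",
    "FrameScaler",
    "fit_reference_scaler",
    "calibrate_threshold",
    "motif_pair_similarity",
    "aggregate_similarity",
    "similarity_table",
    "syllable_accuracy",
    "feature_percent_difference",
]

SIMILARITY_FEATURES = [
    "mean_frequency_hz",
    "wiener_entropy",
    "goodness_of_pitch",
    "frequency_modulation",
    "pitch_hz",
]

#: frames more than this far below the loudest frame are treated as silence
ACTIVITY_RANGE_DB = 30.0


@dataclass(frozen=True)
class FrameScaler:
    mean: np.ndarray
    scale: np.ndarray

    def transform(self, frames: pd.DataFrame) -> np.ndarray:
        X = frames[SIMILARITY_FEATURES].to_numpy(dtype=float).copy()
        # unvoiced frames carry no pitch; a fixed 0 keeps them comparable
        X[np.isnan(X)] = 0.0
        return (X - self.mean) / self.scale


def _active_mask(frames: pd.DataFrame) -> np.ndarray:
    amp = frames["amplitude_db"].to_numpy()
    return amp >= amp.max() - ACTIVITY_RANGE_DB


def fit_reference_scaler(frame_sets: list[pd.DataFrame]) -> FrameScaler:
    """Fit the z-scoring used for all frame comparisons on a reference corpus."""
    X = np.vstack([
        f.loc[_active_mask(f), SIMILARITY_FEATURES].to_numpy(dtype=float)
        for f in frame_sets
    ])
    X[np.isnan(X)] = 0.0
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FrameScaler(mean=mean, scale=scale)


def _nearest_distances(
    pupil: pd.DataFrame,
    tutor: pd.DataFrame,
    scaler: FrameScaler,
    window_s: float,
) -> np.ndarray:
    """Min distance from each active pupil frame to tutor frames in-window."""
    pa = _active_mask(pupil)
    ta = _active_mask(tutor)
    if not pa.any() or not ta.any():
        raise ValueError("a motif has no vocalized frames")
    P = scaler.transform(pupil.loc[pa])
    T = scaler.transform(tutor.loc[ta])
    tp = pupil.loc[pa, "time_s"].to_numpy()
    tp = tp - tp.min()
    tt = tutor.loc[ta, "time_s"].to_numpy()
    tt = tt - tt.min()
    D = cdist(P, T)
    out_of_window = np.abs(tp[:, None] - tt[None, :]) > window_s
    D[out_of_window] = np.inf
    return D.min(axis=1)


def motif_pair_similarity(
    pupil_frames: pd.DataFrame,
    tutor_frames: pd.DataFrame,
    scaler: FrameScaler,
    threshold: float,
    window_s: float = 0.05,
) -> float:
    """Asymmetric similarity of one pupil motif to one tutor motif, 0-100.

    Score = 100 x fraction of vocalized pupil frames whose nearest
    in-window tutor frame lies under the calibrated distance threshold.
    """
    if pupil_frames.empty or tutor_frames.empty:
        raise ValueError("both motifs need at least one frame")
    d = _nearest_distances(pupil_frames, tutor_frames, scaler, window_s)
    return float(100.0 * np.mean(d < threshold))


def calibrate_threshold(
    null_frame_sets: list[pd.DataFrame],
    scaler: FrameScaler,
    quantile: float = 0.05,
    window_s: float = 0.05,
) -> float:
    """Distance threshold = low quantile of unrelated-song frame distances.

    ``null_frame_sets`` are frame tables of mutually unrelated songs; all
    ordered pairs contribute their nearest-frame distances. With the
    default 5% quantile, at most ~5% of unrelated frames pass the
    threshold, pinning the score of unrelated motifs near zero.
    """
    if len(null_frame_sets) < 2:
        raise ValueError("need at least two unrelated songs to calibrate")
    dists = []
    for i, a in enumerate(null_frame_sets):
        for j, b in enumerate(null_frame_sets):
            if i != j:
                dists.append(_nearest_distances(a, b, scaler, window_s))
    return float(np.quantile(np.concatenate(dists), quantile))


def aggregate_similarity(pairwise_scores) -> tuple[float, float]:
    """(motif similarity, maximum similarity) from all pairwise scores.

    Motif similarity is the mean of all scores; maximum similarity is the
    mean of the ``ceil(0.05 n)`` highest — exactly the 10 best of the
    standard 200 comparisons.
    """
    scores = np.asarray(list(pairwise_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty score table")
    n_top = int(np.ceil(0.05 * scores.size))
    top = np.sort(scores)[-n_top:]
    return float(scores.mean()), float(top.mean())


def similarity_table(
    pupil_renditions: list[pd.DataFrame],
    tutor_renditions: list[pd.DataFrame],
    scaler: FrameScaler,
    threshold: float,
    window_s: float = 0.05,
) -> pd.DataFrame:
    """All pupil-x-tutor pairwise similarity scores as a table."""
    rows = []
    for i, p in enumerate(pupil_renditions):
        for j, t in enumerate(tutor_renditions):
            rows.append({
                "pupil_rendition": i,
                "tutor_rendition": j,
                "score": motif_pair_similarity(p, t, scaler, threshold, window_s),
            })
    return pd.DataFrame(rows)


def syllable_accuracy(
    pupil_syllable_renditions: list[pd.DataFrame],
    tutor_syllable_frames: pd.DataFrame,
    scaler: FrameScaler,
    threshold: float,
) -> float:
    """Accuracy (0-100) of a pupil syllable against its matched tutor syllable.

    Unlike motif similarity this is a *local*, time-aligned comparison:
    each pupil frame is compared to the tutor frame at the same relative
    position within the syllable. Per-rendition accuracy is the percentage
    of pupil frames within the distance threshold; accuracies are averaged
    over renditions.
    """
    if not pupil_syllable_renditions:
        raise ValueError("need at least one pupil rendition")
    T = scaler.transform(tutor_syllable_frames)
    if len(T) == 0:
        raise ValueError("tutor syllable has no frames")
    accs = []
    for rend in pupil_syllable_renditions:
        P = scaler.transform(rend)
        if len(P) == 0:
            raise ValueError("pupil rendition has no frames")
        # align by relative position within the syllable
        idx = np.round(np.linspace(0, len(T) - 1, len(P))).astype(int)
        d = np.linalg.norm(P - T[idx], axis=1)
        accs.append(100.0 * np.mean(d < threshold))
    return float(np.mean(accs))


def motif_syllable_accuracy(
    per_type_accuracy: dict[str, float],
) -> float:
    """Average the per-syllable accuracies of a pupil's motif."""
    if not per_type_accuracy:
        raise ValueError("no matched syllable types")
    return float(np.mean(list(per_type_accuracy.values())))


def feature_percent_difference(
    pupil_features: pd.DataFrame,
    tutor_features: pd.DataFrame,
    mapping: dict[str, str],
    feature_cols: list[str] | None = None,
    type_col: str = "type_label",
) -> pd.Series:
    """Per-feature percent difference of a pupil from its tutor.

    For each matched syllable type: average pupil and tutor renditions
    separately, then compute ``100 x (pupil - tutor) / tutor``; the
    per-type values are averaged (unweighted) over the motif's types.
    A zero tutor measurement makes that (type, feature) undefined (NaN,
    with a warning). Unmatched pupil types are skipped.
    """
    cols = feature_cols or [
        "duration_ms", "mean_frequency_hz", "goodness_of_pitch",
        "frequency_modulation", "wiener_entropy",
    ]
    per_type = []
    for p_type, t_type in mapping.items():
        p = pupil_features[pupil_features[type_col] == p_type][cols].mean()
        t = tutor_features[tutor_features[type_col] == t_type][cols].mean()
        zero = t == 0
        if zero.any():
            warnings.warn(
                f"tutor measurement 0 for {list(t.index[zero])} on type {t_type}; "
                "percent difference undefined"
            )
        pct = 100.0 * (p - t) / t.where(~zero)
        per_type.append(pct)
    if not per_type:
        raise ValueError("no matched syllable types")
    return pd.DataFrame(per_type).mean()
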