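"""Syllable typing: clustering, tutor-pupil type matching, omission counts.

Syllables are classified into types by centroid-based clustering (k-means)
on z-scored acoustic features, with the number of types chosen by the
silhouette criterion when not given. A manual-override table reproduces
the usual hand-correction of obvious misclassifications. Pupil types are
mapped onto tutor types by optimal one-to-one assignment of cluster
centroids with a distance gate; tutor types left unmatched are candidate
omissions, pupil types left unmatched are improvisations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "CLUSTER_FEATURES",
    "TypeAssignment",
    "TypeMapping",
    "OmissionReport",
    "cluster_syllables",
    "apply_overrides",
    "map_pupil_to_tutor_types",
    "omission_report",
]

CLUSTER_FEATURES = [
    "duration_ms",
    "mean_frequency_hz",
    "wiener_entropy",
    "goodness_of_pitch",
    "frequency_modulation",
]


@dataclass
class TypeAssignment:
    """Cluster labels plus the standardization used to compute them."""

    labels: pd.Series                      # syllable index -> type label (str)
    centroids: pd.DataFrame                # type label -> raw-space feature centroid
    feature_cols: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def types(self) -> list[str]:
        return list(self.centroids.index)

    def standardized_centroids(self) -> np.ndarray:
        return (self.centroids.to_numpy() - self.scaler_mean) / self.scaler_scale


def _zscore(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def cluster_syllables(
    features: pd.DataFrame,
    k: int | str = "auto",
    seed: int = 0,
    feature_cols: list[str] | None = None,
    k_max: int = 10,
    min_silhouette: float = 0.5,
) -> TypeAssignment:
    """Partition syllables into types by k-means on z-scored features.

    With ``k="auto"`` the silhouette score is maximized over 2..``k_max``;
    if even the best split scores below ``min_silhouette`` the corpus is
    treated as a single type (the silhouette is undefined at k=1, so a
    floor on cluster quality stands in for it). Deterministic given
    ``seed``. Type labels are ``"t0", "t1", ...`` ordered by increasing
    mean frequency so labels are stable across runs.
    """
    cols = feature_cols or CLUSTER_FEATURES
    X_raw = features[cols].to_numpy(dtype=float)
    n = len(X_raw)
    if isinstance(k, int) and n < k:
        raise ValueError(f"need at least k={k} syllables, got {n}")
    if n == 0:
        raise ValueError("empty feature table")
    X, mean, scale = _zscore(X_raw)

    if k == "auto":
        best_k, best_score, best_model = 1, -np.inf, None
        for kk in range(2, min(k_max, n - 1) + 1):
            model = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
            if len(np.unique(model.labels_)) < 2:
                continue
            score = silhouette_score(X, model.labels_)
            if score > best_score:
                best_k, best_score, best_model = kk, score, model
        if best_model is None or best_score < min_silhouette:
            labels_idx = np.zeros(n, dtype=int)
            k_used, sil = 1, float("nan")
        else:
            labels_idx = best_model.labels_
            k_used, sil = best_k, float(best_score)
    else:
        model = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        labels_idx = model.labels_
        k_used = k
        sil = (float(silhouette_score(X, labels_idx))
               if len(np.unique(labels_idx)) > 1 else float("nan"))

    # relabel clusters by ascending mean frequency for stability
    centroids_raw = np.vstack([
        X_raw[labels_idx == c].mean(axis=0) for c in range(k_used)
    ])
    mf_col = cols.index("mean_frequency_hz") if "mean_frequency_hz" in cols else 0
    order = np.argsort(centroids_raw[:, mf_col])
    remap = {old: f"t{new}" for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in labels_idx], index=features.index,
                       name="type_label")
    centroids = pd.DataFrame(
        centroids_raw[order], columns=cols,
        index=[f"t{i}" for i in range(k_used)],
    )
    return TypeAssignment(
        labels=labels, centroids=centroids, feature_cols=list(cols),
        scaler_mean=mean, scaler_scale=scale,
        diagnostics={"k": k_used, "silhouette": sil},
    )


def apply_overrides(assignment: TypeAssignment, overrides: pd.DataFrame) -> TypeAssignment:
    """Apply manual corrections (columns ``syllable_id, corrected_label``)."""
    labels = assignment.labels.copy()
    for _, row in overrides.iterrows():
        labels.loc[row["syllable_id"]] = row["corrected_label"]
    return TypeAssignment(
        labels=labels, centroids=assignment.centroids,
        feature_cols=assignment.feature_cols,
        scaler_mean=assignment.scaler_mean, scaler_scale=assignment.scaler_scale,
        diagnostics={**assignment.diagnostics, "overrides": len(overrides)},
    )


@dataclass(frozen=True)
class TypeMapping:
    mapping: dict[str, str]           # pupil type -> tutor type
    unmatched_tutor: frozenset[str]   # candidate omissions
    unmatched_pupil: frozenset[str]   # improvisations
    distances: pd.DataFrame


def map_pupil_to_tutor_types(
    pupil: TypeAssignment,
    tutor: TypeAssignment,
    max_distance: float = np.inf,
) -> TypeMapping:
    """Match pupil types to tutor types by optimal one-to-one assignment.

    Centroids are compared in the tutor's standardized feature space; the
    rectangular assignment minimizing total distance is gated by
    ``max_distance``, so dissimilar pairs stay unmatched.
    """
    if not len(pupil.centroids) or not len(tutor.centroids):
        raise ValueError("both assignments must contain at least one type")
    if pupil.feature_cols != tutor.feature_cols:
        raise ValueError("assignments use different feature spaces")
    tz = tutor.standardized_centroids()
    pz = (pupil.centroids.to_numpy() - tutor.scaler_mean) / tutor.scaler_scale
    D = np.linalg.norm(pz[:, None, :] - tz[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(D)
    mapping = {}
    for r, c in zip(rows, cols):
        if D[r, c] <= max_distance:
            mapping[pupil.types[r]] = tutor.types[c]
    unmatched_tutor = frozenset(tutor.types) - frozenset(mapping.values())
    unmatched_pupil = frozenset(pupil.types) - frozenset(mapping.keys())
    return TypeMapping(
        mapping=mapping,
        unmatched_tutor=unmatched_tutor,
        unmatched_pupil=unmatched_pupil,
        distances=pd.DataFrame(D, index=pupil.types, columns=tutor.types),
    )


@dataclass(frozen=True)
class OmissionReport:
    tutor_types: frozenset[str]
    pupil_types: frozenset[str]
    missing_labels: frozenset[str]
    n_missing: int
    syllables_per_motif_pupil: float
    syllables_per_motif_tutor: float


def omission_report(
    mapping: TypeMapping,
    pupil_motifs: list[list[str]],
    tutor_motifs: list[list[str]],
) -> OmissionReport:
    """Count omitted tutor types and mean syllables per complete motif.

    ``pupil_motifs``/``tutor_motifs`` are sequences of complete motif
    renditions (partial motifs at file boundaries are the caller's to
    exclude). Improvised pupil types (unmatched on the pupil side) are
    never counted as omissions.
    """
    if not pupil_motifs or not tutor_motifs:
        raise ValueError("need at least one complete motif per bird")
    tutor_types = frozenset().union(*[set(m) for m in tutor_motifs])
    pupil_types = frozenset().union(*[set(m) for m in pupil_motifs])
    missing = frozenset(mapping.unmatched_tutor)
    return OmissionReport(
        tutor_types=tutor_types,
        pupil_types=pupil_types,
        missing_labels=missing,
        n_missing=len(missing),
        syllables_per_motif_pupil=float(np.mean([len(m) for m in pupil_motifs])),
        syllables_per_motif_tutor=float(np.mean([len(m) for m in tutor_motifs])),
    )
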