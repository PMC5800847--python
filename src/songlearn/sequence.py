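"""Syllable-transition entropy and amount-of-singing quantification.

Song syntax stereotypy is measured from the first-order transition matrix
of syllable types. For each type *t* (a row of the matrix) the transition
probabilities are the row-normalized counts, the per-type entropy is the
Shannon entropy of that row, and the per-type weighted entropy multiplies
it by the row's share of all transitions. The overall score sums the
weighted entropies — a weight-weighted average over types — so that a
deterministic syntax scores 0 and more variable syntax scores higher
(higher transition entropy = lower stereotypy). Natural log by default;
``base=2`` gives bits.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransitionMatrix",
    "TransitionEntropyResult",
    "build_transition_matrix",
    "transition_entropy",
    "amount_of_singing",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """First-order transition counts between syllable types."""

    counts: pd.DataFrame  # square, from-type rows x to-type columns

    def __post_init__(self) -> None:
        c = self.counts
        if list(c.index) != list(c.columns):
            raise ValueError("counts must be square with matching labels")
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def probabilities(self) -> pd.DataFrame:
        """Row-normalized counts; rows with zero transitions stay NaN."""
        rs = self.row_sums
        probs = self.counts.div(rs.where(rs > 0), axis=0)
        return probs

    @property
    def zero_rows(self) -> frozenset[str]:
        return frozenset(self.row_sums.index[self.row_sums == 0])


@dataclass(frozen=True)
class TransitionEntropyResult:
    per_type_entropy: dict[str, float]
    per_type_weight: dict[str, float]
    per_type_weighted: dict[str, float]
    overall: float            # sum of weighted per-type entropies (canonical)
    unweighted_mean: float    # plain mean of per-type entropies, for reference
    base: str


def build_transition_matrix(
    sequences: list[list[str]] | list[tuple[str, ...]],
    labels: list[str] | None = None,
) -> TransitionMatrix:
    """Count adjacent ordered pairs within each sequence.

    Transitions never cross sequence (file/bout) boundaries. ``labels``
    fixes the matrix axes (useful to include types a bird never leads
    from); otherwise the sorted set of observed labels is used.
    """
    pairs = [(s[i], s[i + 1]) for s in sequences for i in range(len(s) - 1)]
    if not pairs:
        raise ValueError("need at least one sequence of length >= 2")
    if labels is None:
        labels = sorted({x for s in sequences for x in s})
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a, b in pairs:
        counts.loc[a, b] += 1
    return TransitionMatrix(counts=counts)


def transition_entropy(
    matrix: TransitionMatrix, base: str = "e"
) -> TransitionEntropyResult:
    """Per-type, weighted and overall transition entropy of a song.

    ``Entropy_t = -sum_j p_tj log p_tj`` with ``0 log 0 = 0``;
    ``weight_t = row_sum_t / total``; ``Entropy_tw = Entropy_t * weight_t``;
    ``overall = sum_t Entropy_tw``. Zero-count rows contribute zero entropy
    with zero weight.
    """
    if base not in ("e", "2"):
        raise ValueError("base must be 'e' or '2'")
    total = matrix.total
    if total == 0:
        raise ValueError("transition matrix is empty (total count 0)")
    log = np.log if base == "e" else np.log2

    per_entropy: dict[str, float] = {}
    per_weight: dict[str, float] = {}
    per_weighted: dict[str, float] = {}
    for t in matrix.labels:
        row = matrix.counts.loc[t].to_numpy(dtype=float)
        rs = row.sum()
        if rs == 0:
            h = 0.0
            w = 0.0
        else:
            p = row / rs
            nz = p[p > 0]
            h = float(-(nz * log(nz)).sum())
            w = float(rs / total)
        per_entropy[t] = h
        per_weight[t] = w
        per_weighted[t] = h * w
    return TransitionEntropyResult(
        per_type_entropy=per_entropy,
        per_type_weight=per_weight,
        per_type_weighted=per_weighted,
        overall=float(sum(per_weighted.values())),
        unweighted_mean=float(np.mean(list(per_entropy.values()))),
        base=base,
    )


def _as_time(value) -> _dt.time:
    if isinstance(value, _dt.time):
        return value
    return _dt.time.fromisoformat(value)


def amount_of_singing(
    manifest: pd.DataFrame,
    window_start="08:00",
    window_end="12:00",
) -> pd.DataFrame:
    """Total syllables sung per bird per day within a daily time window.

    Counts ``n_syllables`` over manifest rows whose timestamp's time of day
    falls in ``[window_start, window_end)`` (half-open). Returns one row
    per (bird_id, date); a bird with no in-window files gets a zero row
    with a warning.
    """
    start, end = _as_time(window_start), _as_time(window_end)
    if manifest.empty:
        warnings.warn("empty manifest: no singing to count")
        return pd.DataFrame(columns=["bird_id", "date", "n_syllables"])
    ts = pd.to_datetime(manifest["timestamp"])
    tod = ts.dt.time
    in_window = (tod >= start) & (tod < end)
    df = manifest.assign(_date=ts.dt.date, _in=in_window)
    out = (
        df[df["_in"]]
        .groupby(["bird_id", "_date"], as_index=False)["n_syllables"].sum()
        .rename(columns={"_date": "date"})
    )
    for bird in df["bird_id"].unique():
        if bird not in set(out["bird_id"]):
            warnings.warn(f"bird {bird}: no files in the singing window")
            out = pd.concat([
                out,
                pd.DataFrame([{"bird_id": bird,
                               "date": df.loc[df["bird_id"] == bird, "_date"].iloc[0],
                               "n_syllables": 0}]),
            ], ignore_index=True)
    return out.sort_values(["bird_id", "date"]).reset_index(drop=True)
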