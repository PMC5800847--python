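"""Trial-by-trial variability, social-context modulation, and qPCR fold-changes.

Vocal variability is expressed as the coefficient of variation (CV =
sample SD / mean, n-1 denominator) of an acoustic feature over renditions
of a syllable type, averaged (unweighted) over a bird's syllable types.
Social-context modulation of pitch stability is the ratio
``CV_UDS / CV_DS`` of the constant-fundamental-frequency (cFF) CVs of the
same syllable sung undirected (UDS) versus female-directed (DS); in normal
adults DS is more stereotyped, so the ratio exceeds 1. Gene expression
from qPCR cycle thresholds uses the comparative-Ct method:
``fold = 2^-ΔΔCt`` with ``ΔCt = Ct_target - Ct_reference`` and ``ΔΔCt``
taken against the control group's mean ΔCt.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cv",
    "feature_cv",
    "cff_context_ratio",
    "developmental_trajectory",
    "group_compare",
    "delta_delta_ct",
    "ExpressionResult",
]


def cv(values) -> float:
    """Coefficient of variation: sample SD (n-1) over mean."""
    x = np.asarray(list(values), dtype=float)
    if len(x) < 2:
        raise ValueError("CV needs at least two values")
    m = x.mean()
    if m == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / m)


def feature_cv(
    features: pd.DataFrame,
    value_cols: list[str],
    bird_col: str = "bird_id",
    type_col: str = "type_label",
    extra_group_cols: list[str] | None = None,
    min_renditions: int = 10,
) -> pd.DataFrame:
    """Per-bird CV of each acoustic feature, averaged over syllable types.

    CV is computed per (bird, type[, extra groups]) cell over that cell's
    renditions; cells with fewer than ``min_renditions`` renditions are
    excluded with a warning, as are cells with zero mean. The per-type
    CVs are then averaged with equal weight per bird. Returns long-format
    rows (bird[, extras], feature, cv, n_types).
    """
    extras = extra_group_cols or []
    group_cols = [bird_col, *extras, type_col]
    rows = []
    for key, cell in features.groupby(group_cols):
        if len(cell) < min_renditions:
            warnings.warn(f"cell {key}: only {len(cell)} renditions, excluded")
            continue
        key = key if isinstance(key, tuple) else (key,)
        for col in value_cols:
            vals = cell[col].dropna()
            if len(vals) < 2:
                continue
            m = vals.mean()
            if m == 0:
                warnings.warn(f"cell {key} feature {col}: zero mean, undefined CV")
                continue
            rows.append({
                **dict(zip(group_cols, key)),
                "feature": col,
                "cv": float(vals.std(ddof=1) / abs(m)),
            })
    per_type = pd.DataFrame(rows)
    if per_type.empty:
        return pd.DataFrame(columns=[bird_col, *extras, "feature", "cv", "n_types"])
    out = (
        per_type.groupby([bird_col, *extras, "feature"], as_index=False)
        .agg(cv=("cv", "mean"), n_types=("cv", "size"))
    )
    return out


def cff_context_ratio(
    cff: pd.DataFrame,
    bird_col: str = "bird_id",
    type_col: str = "type_label",
    context_col: str = "context",
    value_col: str = "cff_hz",
    min_renditions: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """UDS/DS cFF-variability ratio per syllable and per bird.

    Only rows with a detected cFF enter. For each (bird, syllable type)
    present in both contexts with at least ``min_renditions`` renditions
    each: ``ratio = CV_UDS / CV_DS``. Returns ``(per_syllable, per_bird)``
    where the bird summary is the mean ratio over its syllables. Syllables
    absent from one context are excluded with a warning.
    """
    data = cff.dropna(subset=[value_col])
    per_syl_rows = []
    for (bird, typ), cell in data.groupby([bird_col, type_col]):
        cvs = {}
        for ctx in ("UDS", "DS"):
            vals = cell.loc[cell[context_col] == ctx, value_col]
            if len(vals) < min_renditions:
                continue
            cvs[ctx] = float(vals.std(ddof=1) / vals.mean())
        if set(cvs) != {"UDS", "DS"}:
            warnings.warn(
                f"bird {bird} syllable {typ}: missing a context, excluded"
            )
            continue
        if cvs["DS"] == 0:
            warnings.warn(f"bird {bird} syllable {typ}: zero DS CV, excluded")
            continue
        per_syl_rows.append({
            bird_col: bird, type_col: typ,
            "cv_uds": cvs["UDS"], "cv_ds": cvs["DS"],
            "uds_ds_ratio": cvs["UDS"] / cvs["DS"],
        })
    per_syllable = pd.DataFrame(per_syl_rows)
    if per_syllable.empty:
        return per_syllable, pd.DataFrame(columns=[bird_col, "uds_ds_ratio"])
    per_bird = (
        per_syllable.groupby(bird_col, as_index=False)["uds_ds_ratio"].mean()
    )
    return per_syllable, per_bird


def developmental_trajectory(
    summaries: pd.DataFrame,
    value_col: str = "cv",
    age_col: str = "age_d",
    group_cols: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age trajectory of a variability (or performance) summary.

    Returns ``(series, trends)``: per group and age the mean value with SD
    band, and per group the sign and p-value of the fitted linear slope
    over age. A single-age group gets a NaN trend with a warning.
    """
    groups = group_cols or []
    key_cols = groups if groups else [None]
    series = (
        summaries.groupby([*groups, age_col], as_index=False)[value_col]
        .agg(["mean", "std"])
        .reset_index(drop=True)
        if groups else
        summaries.groupby(age_col, as_index=False)[value_col].agg(["mean", "std"])
    )
    trend_rows = []
    grouped = summaries.groupby(groups) if groups else [((), summaries)]
    for key, g in grouped:
        key = key if isinstance(key, tuple) else (key,)
        ages = g[age_col].to_numpy(dtype=float)
        if len(np.unique(ages)) < 2:
            warnings.warn(f"group {key}: single age, trend undefined")
            slope, p = np.nan, np.nan
        else:
            res = stats.linregress(ages, g[value_col].to_numpy(dtype=float))
            slope, p = res.slope, res.pvalue
        trend_rows.append({
            **dict(zip(groups, key)),
            "slope": slope,
            "slope_sign": int(np.sign(slope)) if np.isfinite(slope) else 0,
            "p_value": p,
        })
    return series, pd.DataFrame(trend_rows)


def group_compare(
    values_a,
    values_b,
    test: str = "mann_whitney",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Two-group comparison: Mann-Whitney U or paired t. Returns (stat, p).

    The exact small-sample Mann-Whitney null distribution is used when both
    groups have n <= 8 and there are no ties (scipy falls back to the
    tie-corrected normal approximation otherwise).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if test == "mann_whitney":
        ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= 8 and not ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method,
                                 use_continuity=False)
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if test == "paired_t":
        if a.size != b.size:
            raise ValueError("paired test requires equal-length matched vectors")
        res = stats.ttest_rel(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


@dataclass(frozen=True)
class ExpressionResult:
    per_sample: pd.DataFrame   # sample, group, gene, mean_ct, replicate_sd, dct, ddct, fold
    group_summary: pd.DataFrame  # group, gene, mean fold, sem


def delta_delta_ct(
    ct: pd.DataFrame,
    target_genes: list[str],
    reference_gene: str,
    control_group: str,
    sample_col: str = "sample",
    group_col: str = "group",
    gene_col: str = "gene",
    ct_col: str = "ct",
) -> ExpressionResult:
    """Comparative-Ct (2^-ΔΔCt) expression fold-changes.

    Technical replicates are averaged per sample x gene (their SD is
    reported); ``ΔCt = Ct_target - Ct_reference`` within each sample;
    ``ΔΔCt`` subtracts the control group's mean ΔCt for that gene;
    ``fold = 2^-ΔΔCt``. Samples missing the reference gene are excluded
    with a warning.
    """
    means = (
        ct.groupby([sample_col, group_col, gene_col], as_index=False)[ct_col]
        .agg(mean_ct="mean", replicate_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0)
    )
    ref = means[means[gene_col] == reference_gene].set_index(sample_col)["mean_ct"]
    rows = []
    for gene in target_genes:
        sub = means[means[gene_col] == gene].copy()
        missing = ~sub[sample_col].isin(ref.index)
        if missing.any():
            warnings.warn(
                f"samples {sorted(sub.loc[missing, sample_col])} lack the "
                f"reference gene {reference_gene}; excluded"
            )
            sub = sub[~missing]
        if sub.empty:
            continue
        sub["dct"] = sub["mean_ct"].to_numpy() - ref.loc[sub[sample_col]].to_numpy()
        ctrl = sub.loc[sub[group_col] == control_group, "dct"]
        if ctrl.empty:
            raise ValueError(f"no control-group samples for gene {gene}")
        sub["ddct"] = sub["dct"] - ctrl.mean()
        sub["fold"] = 2.0 ** (-sub["ddct"])
        rows.append(sub)
    if not rows:
        raise ValueError("no target-gene measurements found")
    per_sample = pd.concat(rows, ignore_index=True)
    group_summary = (
        per_sample.groupby([group_col, gene_col], as_index=False)["fold"]
        .agg(mean_fold="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x))
             if len(x) > 1 else 0.0, n="size")
    )
    return ExpressionResult(per_sample=per_sample, group_summary=group_summary)
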