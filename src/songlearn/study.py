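"""Synthetic cohort study: control-like vs perturbed-like pupils.

This module fixes the *study conditions* for the package's end-to-end
checks: two cohorts of six pupils each, every pupil with its own tutor
motif. Control-like pupils imitate well — no omissions, little sequence
noise, small feature CVs, and a directed-song variance scale of 0.5 (the
female-directed song is more stereotyped than undirected song, so the
UDS/DS cFF-CV ratio sits near 2). Perturbed-like pupils model a learner
with an impaired basal-ganglia song circuit: complete omission of a motif
syllable, frequent order switching / stuttering / truncation, larger
feature CVs, and no context modulation (variance scale 1, ratio near 1).

Running the full pipeline on these cohorts reproduces the canonical
direction of effects: higher transition entropy, higher acoustic-feature
CVs, lower tutor-pupil motif similarity, nonzero syllable omissions, and
abolished social-context modulation in the perturbed cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segment import FrameConfig, compute_frames
from .sequence import build_transition_matrix, transition_entropy
from .similarity import (
    aggregate_similarity,
    calibrate_threshold,
    fit_reference_scaler,
    similarity_table,
)
from .synth import (
    BirdSpec,
    CohortSpec,
    MotifTemplate,
    PupilModel,
    generate_rendition,
    make_tutor_template,
    render_waveform,
)
from .variability import cff_context_ratio, feature_cv, group_compare

__all__ = [
    "control_model",
    "perturbed_model",
    "make_study_cohorts",
    "cohort_entropy",
    "cohort_feature_cv",
    "cohort_cff_ratio",
    "cohort_omissions",
    "cohort_similarity",
    "direction_of_effect",
]

N_BIRDS = 6           # birds per cohort, as in the behavioural comparisons
N_RENDITIONS = 40     # renditions per context (the 20-40 per-context range)
AGE_D = 100           # young-adult endpoint age


def control_model(template: MotifTemplate) -> PupilModel:
    """A well-learning pupil: faithful syntax, small CVs, DS more stereotyped."""
    return PupilModel(
        template=template,
        omission_prob={},
        repetition_prob=0.02,
        truncation_prob=0.05,
        order_switch_prob=0.01,
        feature_cv={
            ("duration_ms", "UDS"): 0.03, ("duration_ms", "DS"): 0.03,
            ("fundamental_hz", "UDS"): 0.012, ("fundamental_hz", "DS"): 0.012,
        },
        ds_variance_scale=0.5,
        age_schedule={AGE_D: 1.0},
    )


def perturbed_model(template: MotifTemplate) -> PupilModel:
    """An impaired pupil: omissions, noisy syntax, high CVs, no DS modulation."""
    omit = template.labels[2]  # one mid-motif syllable is never produced
    return PupilModel(
        template=template,
        omission_prob={omit: 1.0},
        repetition_prob=0.15,
        truncation_prob=0.20,
        order_switch_prob=0.15,
        feature_cv={
            ("duration_ms", "UDS"): 0.10, ("duration_ms", "DS"): 0.10,
            ("fundamental_hz", "UDS"): 0.035, ("fundamental_hz", "DS"): 0.035,
        },
        ds_variance_scale=1.0,
        age_schedule={AGE_D: 1.0},
    )


def make_study_cohorts(
    seed: int,
    n_birds: int = N_BIRDS,
    n_renditions: int = N_RENDITIONS,
) -> tuple[CohortSpec, CohortSpec]:
    """Build matched control-like and perturbed-like cohorts.

    Bird *i* of either cohort learns from tutor template ``seed*1000+i``,
    so the two cohorts differ only in their pupil models.
    """
    def birds(kind, make):
        out = []
        for i in range(n_birds):
            template = make_tutor_template(seed=seed * 1000 + i)
            out.append(BirdSpec(
                bird_id=f"{kind}{i}",
                model=make(template),
                ages=(AGE_D,),
                contexts=("UDS", "DS"),
                n_renditions=n_renditions,
            ))
        return tuple(out)

    return (
        CohortSpec(name="control", birds=birds("c", control_model)),
        CohortSpec(name="perturbed", birds=birds("p", perturbed_model)),
    )


def _sequences_per_bird(truth: pd.DataFrame) -> dict[str, list[list[str]]]:
    seqs: dict[str, list[list[str]]] = {}
    for (bird, _file), g in truth.groupby(["bird_id", "file"]):
        seqs.setdefault(bird, []).append(
            list(g.sort_values("syllable_index")["label"])
        )
    return seqs


def cohort_entropy(truth: pd.DataFrame) -> pd.Series:
    """Overall transition entropy per bird from its rendition sequences."""
    out = {}
    for bird, seqs in _sequences_per_bird(truth).items():
        usable = [s for s in seqs if len(s) >= 2]
        tm = build_transition_matrix(usable)
        out[bird] = transition_entropy(tm).overall
    return pd.Series(out, name="overall_entropy")


def cohort_feature_cv(
    truth: pd.DataFrame, feature: str = "duration_ms", min_renditions: int = 10
) -> pd.Series:
    """Per-bird CV of a realized acoustic parameter, averaged over types."""
    uds = truth[truth["context"] == "UDS"]
    table = feature_cv(uds, [feature], type_col="label",
                       min_renditions=min_renditions)
    return table.set_index("bird_id")["cv"]


def cohort_cff_ratio(truth: pd.DataFrame, min_renditions: int = 10) -> pd.Series:
    """Per-bird UDS/DS cFF-CV ratio over harmonic-stack syllables."""
    stacks = truth[truth["fm_sweep_hz"] == 0.0].copy()
    stacks["cff_hz"] = stacks["fundamental_hz"]
    _, per_bird = cff_context_ratio(stacks, type_col="label",
                                    min_renditions=min_renditions)
    return per_bird.set_index("bird_id")["uds_ds_ratio"]


def cohort_omissions(cohort: CohortSpec, truth: pd.DataFrame) -> pd.Series:
    """Tutor syllable types absent from each pupil's entire corpus."""
    out = {}
    for bird in cohort.birds:
        sung = set(truth.loc[truth["bird_id"] == bird.bird_id, "label"])
        out[bird.bird_id] = len(set(bird.model.template.labels) - sung)
    return pd.Series(out, name="n_missing")


def _motif_frames(
    model: PupilModel,
    context: str,
    n: int,
    rng: np.random.Generator,
    sample_rate_hz: int,
    cfg: FrameConfig,
) -> list[pd.DataFrame]:
    frames = []
    while len(frames) < n:
        rend = generate_rendition(model, context, AGE_D, rng)
        if len(rend) == 0:
            continue
        wave, _ = render_waveform(rend, sample_rate_hz,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        frames.append(compute_frames(wave, sample_rate_hz, cfg))
    return frames


def cohort_similarity(
    seed: int,
    n_birds: int = N_BIRDS,
    n_pupil: int = 10,
    n_tutor: int = 5,
    sample_rate_hz: int = 22050,
    step_ms: float = 3.0,
) -> pd.DataFrame:
    """Tutor-pupil motif similarity per bird for both cohorts.

    Audio is synthesized for ``n_pupil`` pupil and ``n_tutor`` tutor motif
    renditions per bird (a scaled-down version of the 20 x 10 design; the
    aggregation rules are identical). The distance threshold is calibrated
    once from the mutually unrelated tutor songs.
    """
    cfg = FrameConfig(step_ms=step_ms)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))

    templates = [make_tutor_template(seed=seed * 1000 + i) for i in range(n_birds)]

    def tutor_model(t):
        m = control_model(t)
        # tutors render their own song with minimal trial-to-trial noise
        return PupilModel(template=t, feature_cv={
            ("duration_ms", "UDS"): 0.02, ("fundamental_hz", "UDS"): 0.008,
        }, age_schedule={AGE_D: 1.0})

    tutor_frames = {
        i: _motif_frames(tutor_model(t), "UDS", n_tutor, rng, sample_rate_hz, cfg)
        for i, t in enumerate(templates)
    }
    null_set = [tutor_frames[i][0] for i in range(n_birds)]
    scaler = fit_reference_scaler(null_set)
    threshold = calibrate_threshold(null_set, scaler)

    rows = []
    for kind, make in (("control", control_model), ("perturbed", perturbed_model)):
        for i, t in enumerate(templates):
            pupil = _motif_frames(make(t), "UDS", n_pupil, rng, sample_rate_hz, cfg)
            table = similarity_table(pupil, tutor_frames[i], scaler, threshold)
            mean_sim, max_sim = aggregate_similarity(table["score"])
            rows.append({"cohort": kind, "bird_id": f"{kind[0]}{i}",
                         "motif_similarity": mean_sim, "max_similarity": max_sim})
    return pd.DataFrame(rows)


def direction_of_effect(seed: int, include_similarity: bool = True) -> dict:
    """Run the two-cohort study and test every canonical effect direction.

    Returns a dict of per-cohort means and two-sided Mann-Whitney p-values
    for: transition entropy, duration CV, UDS/DS cFF-CV ratio, omission
    counts, and (optionally) motif similarity.
    """
    from .synth import generate_corpus
    import tempfile

    control, perturbed = make_study_cohorts(seed)
    with tempfile.TemporaryDirectory() as tmp:
        _, truth_c = generate_corpus(control, f"{tmp}/c", seed=seed + 1,
                                     write_audio=False)
        _, truth_p = generate_corpus(perturbed, f"{tmp}/p", seed=seed + 2,
                                     write_audio=False)

    results: dict = {}

    def compare(name, a: pd.Series, b: pd.Series):
        stat, p = group_compare(a, b, test="mann_whitney")
        results[name] = {
            "control_mean": float(a.mean()),
            "perturbed_mean": float(b.mean()),
            "U": stat,
            "p_value": p,
        }

    compare("entropy", cohort_entropy(truth_c), cohort_entropy(truth_p))
    compare("duration_cv", cohort_feature_cv(truth_c), cohort_feature_cv(truth_p))
    compare("uds_ds_ratio", cohort_cff_ratio(truth_c), cohort_cff_ratio(truth_p))
    compare("omissions",
            cohort_omissions(control, truth_c).astype(float),
            cohort_omissions(perturbed, truth_p).astype(float))

    if include_similarity:
        sim = cohort_similarity(seed)
        compare(
            "motif_similarity",
            sim.loc[sim["cohort"] == "control"].set_index("bird_id")["motif_similarity"],
            sim.loc[sim["cohort"] == "perturbed"].set_index("bird_id")["motif_similarity"],
        )
    return results
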