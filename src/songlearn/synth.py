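"""Synthetic song generator with known ground truth.

Zebra-finch-like song is modelled as a *motif*: a fixed ordered sequence of
5-8 distinct syllables, each a harmonic stack (sum of harmonics of a
fundamental) optionally mixed with broadband noise and optionally carrying a
linear frequency sweep. A :class:`PupilModel` perturbs the motif the way an
imperfect learner does: per-syllable omission, adjacent-order switching,
immediate repetition (stuttering), suffix truncation, and trial-by-trial
multiplicative Gaussian noise on the acoustic parameters whose magnitude is
a coefficient of variation (CV), optionally scaled by social context
(directed song, DS, is more stereotyped than undirected song, UDS) and by a
developmental schedule over age.

Because every rendition carries its realized parameters, downstream stages
(segmentation, feature extraction, typing, entropy, similarity, variability)
can be validated against exact ground truth without any recorded bird data.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SyllableTemplate",
    "MotifTemplate",
    "PupilModel",
    "RenditionAnnotation",
    "CohortSpec",
    "BirdSpec",
    "make_tutor_template",
    "generate_rendition",
    "render_waveform",
    "generate_corpus",
]

CONTEXTS = ("UDS", "DS")

#: template parameters that may carry trial-by-trial noise
NOISEABLE_FEATURES = ("duration_ms", "fundamental_hz", "amplitude", "noise_mix")


@dataclass(frozen=True)
class SyllableTemplate:
    """Generative parameters of one syllable type.

    ``noise_mix`` is the fraction of broadband-noise energy (0 = pure
    harmonic stack, 1 = pure noise; controls Wiener entropy downstream).
    ``fm_sweep_hz`` is the total linear sweep of the fundamental across the
    syllable; 0 makes the syllable a flat harmonic stack eligible for
    constant-fundamental-frequency (cFF) analysis.
    """

    label: str
    duration_ms: float
    fundamental_hz: float
    n_harmonics: int = 5
    noise_mix: float = 0.0
    fm_sweep_hz: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be positive")
        if self.fundamental_hz <= 0:
            raise ValueError("fundamental_hz must be positive")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be a positive integer")
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ValueError("noise_mix must lie in [0, 1]")

    @property
    def max_harmonic_hz(self) -> float:
        return (self.fundamental_hz + abs(self.fm_sweep_hz) / 2) * self.n_harmonics


@dataclass(frozen=True)
class MotifTemplate:
    """Ordered syllable templates plus the inter-syllable silence gap."""

    syllables: tuple[SyllableTemplate, ...]
    gap_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.gap_ms <= 0:
            raise ValueError("gap_ms must be positive")
        labels = [s.label for s in self.syllables]
        if len(set(labels)) != len(labels):
            raise ValueError("syllable labels must be unique within a motif")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.syllables)

    def __len__(self) -> int:
        return len(self.syllables)


@dataclass(frozen=True)
class PupilModel:
    """Generative model of an (imperfect) pupil's renditions of a motif.

    ``feature_cv`` maps ``(feature, context)`` to the trial-by-trial CV of
    that template parameter; ``ds_variance_scale`` additionally multiplies
    the noise SD in the DS context (values < 1 make DS more stereotyped).
    ``age_schedule`` maps age in days to a multiplier on all CVs.
    """

    template: MotifTemplate
    omission_prob: dict[str, float] = field(default_factory=dict)
    repetition_prob: float = 0.0
    truncation_prob: float = 0.0
    order_switch_prob: float = 0.0
    feature_cv: dict[tuple[str, str], float] = field(default_factory=dict)
    ds_variance_scale: float = 1.0
    age_schedule: dict[int, float] = field(default_factory=lambda: {100: 1.0})
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.repetition_prob, self.truncation_prob, self.order_switch_prob,
                  *self.omission_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.ds_variance_scale <= 0:
            raise ValueError("ds_variance_scale must be positive")
        for (feat, ctx), cv in self.feature_cv.items():
            if feat not in NOISEABLE_FEATURES:
                raise ValueError(f"unknown noiseable feature {feat!r}")
            if ctx not in CONTEXTS:
                raise ValueError(f"unknown context {ctx!r}")
            if cv < 0:
                raise ValueError("CVs must be nonnegative")
        if any(m <= 0 for m in self.age_schedule.values()):
            raise ValueError("age multipliers must be positive")

    def effective_cv(self, feature: str, context: str, age_d: int) -> float:
        cv = self.feature_cv.get((feature, context), 0.0)
        cv *= self.age_schedule[age_d]
        if context == "DS":
            cv *= self.ds_variance_scale
        return cv


@dataclass(frozen=True)
class RenditionAnnotation:
    """One realized motif rendition: sequence + realized syllable parameters."""

    syllables: tuple[SyllableTemplate, ...]
    gap_ms: float
    context: str
    age_d: int
    timestamp: _dt.datetime | None = None

    @property
    def sequence(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.syllables)

    def __len__(self) -> int:
        return len(self.syllables)


def make_tutor_template(
    n_syllables: int | None = None,
    seed: int = 0,
    *,
    gap_ms: float = 40.0,
    n_harmonics: int = 5,
) -> MotifTemplate:
    """Build a tutor motif of well-separated syllable types.

    Parameters are laid out on permuted grids (duration 60-180 ms,
    fundamental 450-1050 Hz, noise mix 0-0.4) so that syllable types are
    mutually separated in feature space and clustering is well-posed.
    Even-indexed syllables are flat harmonic stacks (``fm_sweep_hz = 0``),
    so every motif contains cFF-eligible syllables. Deterministic in
    ``seed``; with ``n_syllables=None`` the motif length is drawn uniformly
    from 5-8, the species-typical range.
    """
    rng = np.random.default_rng(seed)
    if n_syllables is None:
        n_syllables = int(rng.integers(5, 9))
    if not 2 <= n_syllables <= 26:
        raise ValueError("n_syllables must lie in [2, 26]")

    n = n_syllables
    durations = np.linspace(60.0, 180.0, n)[rng.permutation(n)]
    fundamentals = np.linspace(450.0, 1050.0, n)[rng.permutation(n)]
    noise_mixes = np.linspace(0.0, 0.4, n)[rng.permutation(n)]
    sweeps = np.where(np.arange(n) % 2 == 0, 0.0,
                      rng.choice([-200.0, 200.0], size=n))
    labels = [chr(ord("a") + i) for i in range(n)]
    syllables = tuple(
        SyllableTemplate(
            label=labels[i],
            duration_ms=float(durations[i]),
            fundamental_hz=float(fundamentals[i]),
            n_harmonics=n_harmonics,
            noise_mix=float(noise_mixes[i]),
            fm_sweep_hz=float(sweeps[i]),
        )
        for i in range(n)
    )
    return MotifTemplate(syllables=syllables, gap_ms=gap_ms)


def _realize_syllable(
    syl: SyllableTemplate,
    model: PupilModel,
    context: str,
    age_d: int,
    rng: np.random.Generator,
) -> SyllableTemplate:
    updates: dict[str, float] = {}
    for feat in NOISEABLE_FEATURES:
        cv = model.effective_cv(feat, context, age_d)
        if cv == 0.0:
            continue
        value = getattr(syl, feat) * (1.0 + rng.normal(0.0, cv))
        if feat == "noise_mix":
            value = float(np.clip(value, 0.0, 1.0))
        elif feat == "duration_ms":
            value = max(value, 5.0)
        else:
            value = max(value, 1e-6)
        updates[feat] = float(value)
    return replace(syl, **updates) if updates else syl


def generate_rendition(
    model: PupilModel,
    context: str,
    age_d: int,
    rng: np.random.Generator,
    timestamp: _dt.datetime | None = None,
) -> RenditionAnnotation:
    """Draw one rendition from the pupil model.

    Sequence noise is applied in the fixed order omission -> adjacent swap
    -> immediate repetition -> suffix truncation; feature noise is
    multiplicative Gaussian with the context- and age-effective CV.
    """
    if context not in CONTEXTS:
        raise ValueError(f"unknown context {context!r} (expected UDS or DS)")
    if age_d not in model.age_schedule:
        raise ValueError(f"age {age_d} d not in the model's age schedule")

    kept = [s for s in model.template.syllables
            if rng.random() >= model.omission_prob.get(s.label, 0.0)]
    for i in range(len(kept) - 1):
        if rng.random() < model.order_switch_prob:
            kept[i], kept[i + 1] = kept[i + 1], kept[i]
    with_reps: list[SyllableTemplate] = []
    for s in kept:
        with_reps.append(s)
        if rng.random() < model.repetition_prob:
            with_reps.append(s)
    if with_reps and rng.random() < model.truncation_prob:
        cut = int(rng.integers(1, len(with_reps) + 1))
        with_reps = with_reps[:cut]

    realized = tuple(
        _realize_syllable(s, model, context, age_d, rng) for s in with_reps
    )
    return RenditionAnnotation(
        syllables=realized, gap_ms=model.template.gap_ms,
        context=context, age_d=age_d, timestamp=timestamp,
    )


def _raised_cosine_window(n: int, ramp: int) -> np.ndarray:
    win = np.ones(n)
    ramp = min(ramp, n // 2)
    if ramp > 0:
        edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        win[:ramp] = edge
        win[-ramp:] = edge[::-1]
    return win


def _synthesize_syllable(
    syl: SyllableTemplate, sr: int, rng: np.random.Generator, ramp_ms: float = 5.0
) -> np.ndarray:
    n = max(int(round(syl.duration_ms / 1000.0 * sr)), 2)
    t = np.arange(n) / sr
    dur = n / sr
    # linear sweep centred on the fundamental: f(t) = f0 + sweep*(t/T - 1/2)
    phase_base = syl.fundamental_hz * t + syl.fm_sweep_hz * (t**2 / (2 * dur) - t / 2)
    harm = np.zeros(n)
    for k in range(1, syl.n_harmonics + 1):
        harm += np.sin(2 * np.pi * k * phase_base) / k
    rms = np.sqrt(np.mean(harm**2))
    if rms > 0:
        harm /= rms
    noise = rng.standard_normal(n)
    noise /= np.sqrt(np.mean(noise**2))
    y = np.sqrt(1.0 - syl.noise_mix) * harm + np.sqrt(syl.noise_mix) * noise
    y *= _raised_cosine_window(n, int(round(ramp_ms / 1000.0 * sr)))
    return 0.2 * syl.amplitude * y


def render_waveform(
    rendition: RenditionAnnotation,
    sample_rate_hz: int = 44100,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Synthesize a rendition into audio plus sample-accurate annotations.

    Returns ``(waveform, annotations)`` where the waveform is float in
    [-1, 1] and the annotation table has columns ``syllable_index, label,
    onset_s, offset_s``. The broadband-noise component is drawn from a
    generator seeded with ``seed`` so rendering is reproducible.
    """
    if len(rendition) == 0:
        raise ValueError("cannot render an empty rendition")
    worst = max(s.max_harmonic_hz for s in rendition.syllables)
    if sample_rate_hz < 2 * worst:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz below Nyquist requirement for "
            f"highest harmonic {worst:.0f} Hz"
        )
    rng = np.random.default_rng(seed)
    gap = np.zeros(int(round(rendition.gap_ms / 1000.0 * sample_rate_hz)))
    lead = np.zeros(int(round(0.05 * sample_rate_hz)))  # 50 ms leading silence

    pieces = [lead]
    rows = []
    cursor = len(lead)
    for i, syl in enumerate(rendition.syllables):
        audio = _synthesize_syllable(syl, sample_rate_hz, rng)
        rows.append({
            "syllable_index": i,
            "label": syl.label,
            "onset_s": cursor / sample_rate_hz,
            "offset_s": (cursor + len(audio)) / sample_rate_hz,
        })
        pieces.append(audio)
        cursor += len(audio)
        if i < len(rendition) - 1:
            pieces.append(gap)
            cursor += len(gap)
    pieces.append(lead)
    wave = np.concatenate(pieces)
    peak = np.max(np.abs(wave))
    if peak > 1.0:
        wave = wave / peak
    return wave, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# corpus generation


@dataclass(frozen=True)
class BirdSpec:
    """One bird in a cohort: its pupil model plus a recording plan."""

    bird_id: str
    model: PupilModel
    ages: tuple[int, ...] = (100,)
    contexts: tuple[str, ...] = ("UDS",)
    n_renditions: int = 20
    day_start: _dt.time = _dt.time(6, 0)
    day_end: _dt.time = _dt.time(14, 0)
    date: _dt.date = _dt.date(2025, 6, 1)


@dataclass(frozen=True)
class CohortSpec:
    name: str
    birds: tuple[BirdSpec, ...]

    @staticmethod
    def from_yaml(path) -> "CohortSpec":
        """Load a cohort description from YAML.

        Expected structure::

            name: control
            gap_ms: 40
            birds:
              - bird_id: c1
                template_seed: 7
                n_syllables: 5
                ages: [65, 80, 100]
                contexts: [UDS, DS]
                n_renditions: 20
                omission_prob: {c: 0.5}
                repetition_prob: 0.1
                truncation_prob: 0.05
                order_switch_prob: 0.05
                feature_cv:
                  duration_ms: {UDS: 0.08, DS: 0.08}
                  fundamental_hz: {UDS: 0.02, DS: 0.02}
                ds_variance_scale: 0.5
                age_schedule: {65: 1.0, 80: 0.7, 100: 0.5}
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        birds = []
        for b in raw["birds"]:
            template = make_tutor_template(
                b.get("n_syllables"), seed=int(b.get("template_seed", 0)),
                gap_ms=float(raw.get("gap_ms", 40.0)),
            )
            fcv = {
                (feat, ctx): float(cv)
                for feat, per_ctx in b.get("feature_cv", {}).items()
                for ctx, cv in per_ctx.items()
            }
            ages = tuple(int(a) for a in b.get("ages", [100]))
            model = PupilModel(
                template=template,
                omission_prob={str(k): float(v)
                               for k, v in b.get("omission_prob", {}).items()},
                repetition_prob=float(b.get("repetition_prob", 0.0)),
                truncation_prob=float(b.get("truncation_prob", 0.0)),
                order_switch_prob=float(b.get("order_switch_prob", 0.0)),
                feature_cv=fcv,
                ds_variance_scale=float(b.get("ds_variance_scale", 1.0)),
                age_schedule={int(k): float(v)
                              for k, v in b.get("age_schedule",
                                                {a: 1.0 for a in ages}).items()},
            )
            birds.append(BirdSpec(
                bird_id=str(b["bird_id"]), model=model, ages=ages,
                contexts=tuple(b.get("contexts", ["UDS"])),
                n_renditions=int(b.get("n_renditions", 20)),
            ))
        return CohortSpec(name=str(raw["name"]), birds=tuple(birds))


def _rendition_timestamps(bird: BirdSpec, n: int) -> list[_dt.datetime]:
    start = _dt.datetime.combine(bird.date, bird.day_start)
    end = _dt.datetime.combine(bird.date, bird.day_end)
    span = (end - start).total_seconds()
    return [start + _dt.timedelta(seconds=span * i / max(n - 1, 1)) for i in range(n)]


def generate_corpus(
    cohort: CohortSpec,
    out_dir,
    seed: int = 0,
    sample_rate_hz: int = 44100,
    write_audio: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a cohort's WAV corpus, manifest and ground-truth annotations.

    Returns ``(manifest, ground_truth)``; both are also written to
    ``manifest.csv`` / ``ground_truth.csv`` under ``out_dir``. Per-bird RNG
    substreams are spawned from the single global seed, so the corpus is
    byte-identical across runs. ``write_audio=False`` produces the tables
    only (useful for sequence/feature analyses that never touch audio).
    """
    from pathlib import Path

    from scipy.io import wavfile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, truth_rows = [], []
    root_ss = np.random.SeedSequence(seed)
    bird_streams = root_ss.spawn(len(cohort.birds))

    for bird, stream in zip(cohort.birds, bird_streams):
        rng = np.random.default_rng(stream)
        for age in bird.ages:
            for context in bird.contexts:
                stamps = _rendition_timestamps(bird, bird.n_renditions)
                for r, ts in enumerate(stamps):
                    rend = generate_rendition(bird.model, context, age, rng, ts)
                    fname = (f"{bird.bird_id}_{age}d_{context}_"
                             f"{ts.strftime('%Y%m%dT%H%M%S')}_{r:03d}.wav")
                    if len(rend) > 0 and write_audio:
                        render_seed = int(rng.integers(0, 2**31 - 1))
                        wave, ann = render_waveform(rend, sample_rate_hz,
                                                    seed=render_seed)
                        wavfile.write(out / fname,
                                      sample_rate_hz,
                                      (wave * 32767).astype(np.int16))
                    else:
                        ann = pd.DataFrame({
                            "syllable_index": range(len(rend)),
                            "label": rend.sequence,
                            "onset_s": np.nan, "offset_s": np.nan,
                        })
                    manifest_rows.append({
                        "file": fname, "bird_id": bird.bird_id,
                        "cohort": cohort.name, "age_d": age,
                        "context": context, "timestamp": ts.isoformat(),
                        "rendition": r, "n_syllables": len(rend),
                    })
                    for (_, row), syl in zip(ann.iterrows(), rend.syllables):
                        truth_rows.append({
                            "file": fname, "bird_id": bird.bird_id,
                            "cohort": cohort.name, "age_d": age,
                            "context": context, "rendition": r,
                            "syllable_index": int(row["syllable_index"]),
                            "label": syl.label,
                            "onset_s": row["onset_s"],
                            "offset_s": row["offset_s"],
                            "duration_ms": syl.duration_ms,
                            "fundamental_hz": syl.fundamental_hz,
                            "noise_mix": syl.noise_mix,
                            "fm_sweep_hz": syl.fm_sweep_hz,
                            "amplitude": syl.amplitude,
                        })
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    return manifest, truth
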