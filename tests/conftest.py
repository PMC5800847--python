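import numpy as np
import pandas as pd
import pytest

from songlearn import (
    MotifTemplate,
    RenditionAnnotation,
    SyllableTemplate,
    compute_frames,
    make_tutor_template,
    render_waveform,
)

SR = 22050  # test sample rate: light, still well above every harmonic


@pytest.fixture(scope="session")
def render_motif():
    """Factory: render a motif template to a frame-feature table."""

    def _render(template: MotifTemplate, seed: int = 0, sr: int = SR,
                replace_with_noise: int | None = None) -> pd.DataFrame:
        syls = []
        for i, s in enumerate(template.syllables):
            if replace_with_noise is not None and i == replace_with_noise:
                s = SyllableTemplate(s.label, s.duration_ms, s.fundamental_hz,
                                     s.n_harmonics, noise_mix=1.0)
            syls.append(s)
        rend = RenditionAnnotation(tuple(syls), template.gap_ms, "UDS", 100)
        wave, _ = render_waveform(rend, sr, seed=seed)
        return compute_frames(wave, sr)

    return _render


@pytest.fixture(scope="session")
def render_syllable():
    """Factory: render one syllable; returns (frames, onset_s, offset_s)."""

    def _render(syllable: SyllableTemplate, seed: int = 0, sr: int = SR):
        rend = RenditionAnnotation((syllable,), 40.0, "UDS", 100)
        wave, ann = render_waveform(rend, sr, seed=seed)
        frames = compute_frames(wave, sr)
        return frames, float(ann["onset_s"][0]), float(ann["offset_s"][0])

    return _render


@pytest.fixture(scope="session")
def template_feature_table():
    """Factory: a per-syllable feature table drawn around template values.

    Mimics what the acoustic pipeline would measure for ``n_reps``
    renditions of each syllable type, with small multiplicative noise, so
    clustering tests have exact ground-truth labels.
    """

    def _make(template: MotifTemplate, n_reps: int = 50, noise: float = 0.02,
              seed: int = 0, drop_labels: tuple[str, ...] = ()) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n_reps):
            for s in template.syllables:
                if s.label in drop_labels:
                    continue
                rows.append({
                    "label": s.label,
                    "duration_ms": s.duration_ms * (1 + rng.normal(0, noise)),
                    "mean_frequency_hz": 2 * s.fundamental_hz
                    * (1 + rng.normal(0, noise)),
                    "wiener_entropy": -8.0 * (1 - s.noise_mix)
                    * (1 + rng.normal(0, noise)),
                    "goodness_of_pitch": 0.8 * (1 - s.noise_mix)
                    + rng.normal(0, 0.01),
                    "frequency_modulation": 10.0 * abs(s.fm_sweep_hz)
                    + rng.normal(0, 20.0),
                })
        return pd.DataFrame(rows)

    return _make


@pytest.fixture(scope="session")
def tutor5():
    return make_tutor_template(5, seed=1)
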