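"""Segment a rendered song and measure per-syllable acoustic features.

A noiseless motif is synthesized, cut into syllables by the amplitude
segmenter, and each syllable is summarized (duration, mean frequency,
Wiener entropy, goodness of pitch, frequency modulation) including
constant-fundamental-frequency (cFF) detection for harmonic stacks.
"""

import numpy as np

from songlearn import (
    PupilModel,
    compute_frames,
    generate_rendition,
    make_tutor_template,
    render_waveform,
    segment_syllables,
)
from songlearn.features import feature_table

template = make_tutor_template(5, seed=1)
model = PupilModel(template=template, age_schedule={100: 1.0})
rendition = generate_rendition(model, "UDS", 100, np.random.default_rng(0))
wave, truth = render_waveform(rendition, 22050, seed=1)

frames = compute_frames(wave, 22050)
segments = segment_syllables(frames)
features = feature_table(frames, segments)

print(features[["onset_s", "offset_s", "duration_ms", "mean_frequency_hz",
                "wiener_entropy", "cff_hz"]].round(3).to_string(index=False))
print("\nGround-truth onsets:", truth["onset_s"].round(3).tolist())

# Detected boundaries agree with the generator's sample-accurate ones to
# within a frame step; cff_hz is present only for flat harmonic stacks and
# recovers their programmed fundamental within ~1%.
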