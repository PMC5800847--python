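"""Generate a small synthetic song corpus with exact ground truth.

One pupil learns a 5-syllable tutor motif; we write 10 undirected-song
renditions as WAV files plus a manifest and a ground-truth annotation
table (onset/offset, label, and the realized acoustic parameters of every
syllable).
"""

import tempfile

from songlearn import BirdSpec, CohortSpec, PupilModel, generate_corpus, make_tutor_template

template = make_tutor_template(5, seed=1)
model = PupilModel(
    template=template,
    repetition_prob=0.1,          # occasional stuttering
    feature_cv={("duration_ms", "UDS"): 0.05},
    age_schedule={100: 1.0},
)
cohort = CohortSpec(name="demo", birds=(
    BirdSpec(bird_id="pupil1", model=model, n_renditions=10),
))

with tempfile.TemporaryDirectory() as out:
    manifest, truth = generate_corpus(cohort, out, seed=7, sample_rate_hz=22050)
    print(manifest[["file", "context", "n_syllables"]].head().to_string(index=False))
    print(f"\n{len(manifest)} WAV files, {len(truth)} annotated syllables.")
    print("First rendition's ground truth:")
    print(truth[truth["rendition"] == 0][
        ["label", "onset_s", "offset_s", "duration_ms", "fundamental_hz"]
    ].to_string(index=False))

# The n_syllables column varies when stuttering duplicates a syllable; the
# ground-truth table is what every downstream stage is validated against.
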