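"""Asymmetric motif similarity, aggregation rules, accuracy, percent difference."""

import numpy as np
import pandas as pd
import pytest

from songlearn import (
    MotifTemplate,
    SyllableTemplate,
    aggregate_similarity,
    calibrate_threshold,
    feature_percent_difference,
    fit_reference_scaler,
    make_tutor_template,
    motif_pair_similarity,
    similarity_table,
    syllable_accuracy,
)


@pytest.fixture(scope="module")
def calibrated(render_motif):
    """Scaler + threshold calibrated from four mutually unrelated songs."""
    templates = [make_tutor_template(5, seed=s) for s in range(4)]
    null_sets = [render_motif(t, seed=9) for t in templates]
    scaler = fit_reference_scaler(null_sets)
    threshold = calibrate_threshold(null_sets, scaler)
    return scaler, threshold, null_sets


class TestPairSimilarity:
    def test_self_similarity_is_100(self, calibrated):
        scaler, threshold, null_sets = calibrated
        assert motif_pair_similarity(null_sets[0], null_sets[0],
                                     scaler, threshold) == 100.0

    def test_amplitude_scaling_leaves_score_unchanged(self, calibrated,
                                                      render_motif):
        from songlearn import RenditionAnnotation, compute_frames, render_waveform

        scaler, threshold, null_sets = calibrated
        t = make_tutor_template(5, seed=0)
        rend = RenditionAnnotation(t.syllables, t.gap_ms, "UDS", 100)
        wave, _ = render_waveform(rend, 22050, seed=11)
        loud = compute_frames(wave, 22050)
        quiet = compute_frames(0.05 * wave, 22050)
        a = motif_pair_similarity(loud, null_sets[1], scaler, threshold)
        b = motif_pair_similarity(quiet, null_sets[1], scaler, threshold)
        assert a == pytest.approx(b, abs=2.0)

    def test_unrelated_noise_motif_scores_below_10(self, calibrated, render_motif):
        scaler, threshold, null_sets = calibrated
        noise_motif = MotifTemplate(tuple(
            SyllableTemplate(l, 120, 600.0, noise_mix=1.0) for l in "abcde"))
        noise_frames = render_motif(noise_motif, seed=4)
        assert motif_pair_similarity(noise_frames, null_sets[0],
                                     scaler, threshold) < 10.0

    def test_one_of_five_syllables_replaced_scores_near_80(self, calibrated,
                                                           render_motif):
        scaler, threshold, _ = calibrated
        equal = MotifTemplate(tuple(
            SyllableTemplate(l, 100, 450.0 + 120 * i, noise_mix=0.05)
            for i, l in enumerate("abcde")))
        tutor = render_motif(equal, seed=6)
        pupil = render_motif(equal, seed=5, replace_with_noise=2)
        score = motif_pair_similarity(pupil, tutor, scaler, threshold)
        assert score == pytest.approx(80.0, abs=5.0)

    def test_empty_frames_rejected(self, calibrated):
        scaler, threshold, null_sets = calibrated
        with pytest.raises(ValueError):
            motif_pair_similarity(null_sets[0].iloc[:0], null_sets[0],
                                  scaler, threshold)


class TestAggregation:
    def test_20x10_design_yields_exactly_200_scores(self, calibrated):
        scaler, threshold, null_sets = calibrated
        # replicate frame tables: the bookkeeping is what's under test
        pupil = [null_sets[0]] * 20
        tutor = [null_sets[0]] * 10
        table = similarity_table(pupil, tutor, scaler, threshold)
        assert len(table) == 200
        mean_sim, max_sim = aggregate_similarity(table["score"])
        assert mean_sim == max_sim == 100.0

    def test_top_five_percent_rule_on_integer_scores(self):
        mean_sim, max_sim = aggregate_similarity(np.arange(1, 201))
        assert mean_sim == pytest.approx(100.5)
        assert max_sim == pytest.approx(195.5)  # mean of the 10 highest

    def test_all_equal_scores_collapse(self):
        mean_sim, max_sim = aggregate_similarity([42.0] * 30)
        assert mean_sim == max_sim == 42.0

    def test_max_never_below_mean(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(0, 100, size=57)
        mean_sim, max_sim = aggregate_similarity(scores)
        assert max_sim >= mean_sim

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            aggregate_similarity([])


class TestSyllableAccuracy:
    def test_identical_syllables_score_100(self, calibrated, render_syllable):
        scaler, threshold, _ = calibrated
        frames, on, off = render_syllable(SyllableTemplate("a", 100, 600.0))
        syl = frames[(frames.time_s >= on) & (frames.time_s < off)]
        assert syllable_accuracy([syl], syl, scaler, threshold) == 100.0

    def test_syllable_against_silence_scores_0(self, calibrated, render_syllable):
        scaler, threshold, _ = calibrated
        frames, on, off = render_syllable(SyllableTemplate("a", 100, 600.0))
        syl = frames[(frames.time_s >= on) & (frames.time_s < off)]
        from songlearn import compute_frames

        silence = compute_frames(np.zeros(int(0.1 * 22050)), 22050)
        assert syllable_accuracy([syl], silence, scaler, threshold) == 0.0

    def test_accuracy_decreases_with_pupil_noise(self, calibrated,
                                                 render_syllable):
        scaler, threshold, _ = calibrated
        rng = np.random.default_rng(3)

        def renditions(cv, n=8):
            out = []
            for i in range(n):
                f0 = 600.0 * (1 + rng.normal(0, cv))
                dur = 100.0 * (1 + rng.normal(0, cv))
                fr, on, off = render_syllable(
                    SyllableTemplate("a", dur, f0), seed=100 + i)
                out.append(fr[(fr.time_s >= on) & (fr.time_s < off)])
            return out

        tutor_fr, on, off = render_syllable(SyllableTemplate("a", 100, 600.0))
        tutor = tutor_fr[(tutor_fr.time_s >= on) & (tutor_fr.time_s < off)]
        low = syllable_accuracy(renditions(0.02), tutor, scaler, threshold)
        high = syllable_accuracy(renditions(0.10), tutor, scaler, threshold)
        assert low > high


class TestPercentDifference:
    def _tables(self, pupil_factor, n=20, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows_t, rows_p = [], []
        for t in ("t0", "t1"):
            base = {"duration_ms": 100.0, "mean_frequency_hz": 1000.0,
                    "goodness_of_pitch": 0.5, "frequency_modulation": 50.0,
                    "wiener_entropy": -4.0}
            for _ in range(n):
                rows_t.append({"type_label": t, **base})
                rows_p.append({"type_label": t, **{
                    k: v * pupil_factor * (1 + rng.normal(0, noise))
                    for k, v in base.items()}})
        return pd.DataFrame(rows_p), pd.DataFrame(rows_t)

    def test_ten_percent_shift_recovered_exactly(self):
        pupil, tutor = self._tables(1.10)
        pct = feature_percent_difference(pupil, tutor, {"t0": "t0", "t1": "t1"})
        assert pct["duration_ms"] == pytest.approx(10.0)

    def test_identity_gives_zero_for_every_feature(self):
        pupil, tutor = self._tables(1.0)
        pct = feature_percent_difference(pupil, tutor, {"t0": "t0", "t1": "t1"})
        assert np.allclose(pct.to_numpy(), 0.0)

    def test_programmed_bias_recovered_within_sampling_error(self):
        pupil, tutor = self._tables(1.05, noise=0.03, seed=1)
        pct = feature_percent_difference(pupil, tutor, {"t0": "t0", "t1": "t1"})
        assert pct["mean_frequency_hz"] == pytest.approx(5.0, abs=1.5)

    def test_zero_tutor_measurement_flagged_undefined(self):
        pupil, tutor = self._tables(1.0)
        tutor["goodness_of_pitch"] = 0.0
        with pytest.warns(UserWarning):
            pct = feature_percent_difference(pupil, tutor,
                                             {"t0": "t0", "t1": "t1"})
        assert np.isnan(pct["goodness_of_pitch"])

    def test_no_matched_types_rejected(self):
        pupil, tutor = self._tables(1.0)
        with pytest.raises(ValueError):
            feature_percent_difference(pupil, tutor, {})
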