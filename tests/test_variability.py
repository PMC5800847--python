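"""CV statistics, context-modulation ratios, trajectories, tests, ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songlearn import (
    PupilModel,
    cff_context_ratio,
    cv,
    delta_delta_ct,
    developmental_trajectory,
    feature_cv,
    generate_rendition,
    group_compare,
    make_tutor_template,
)


class TestCv:
    def test_hand_computed_value(self):
        assert cv([95, 100, 105]) == pytest.approx(0.05)

    def test_constant_renditions_have_zero_cv(self):
        assert cv([7.0] * 12) == 0.0

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            cv([1.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv([-1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1.0, 1e3), min_size=2, max_size=30),
           st.floats(0.01, 1e3))
    def test_scale_invariance(self, values, factor):
        assert cv(values) == pytest.approx(cv([v * factor for v in values]),
                                           rel=1e-9)


class TestFeatureCv:
    def _table(self, cv_true=0.08, n=200, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for t, mean in (("t0", 100.0), ("t1", 150.0)):
            for _ in range(n):
                rows.append({"bird_id": "b1", "type_label": t,
                             "duration_ms": mean * (1 + rng.normal(0, cv_true))})
        return pd.DataFrame(rows)

    def test_programmed_cv_recovered_within_10_percent(self):
        out = feature_cv(self._table(), ["duration_ms"])
        measured = out.loc[out["feature"] == "duration_ms", "cv"].item()
        assert abs(measured - 0.08) / 0.08 < 0.10

    def test_small_cells_excluded_with_warning(self):
        table = self._table(n=5)
        with pytest.warns(UserWarning):
            out = feature_cv(table, ["duration_ms"], min_renditions=10)
        assert out.empty

    def test_types_averaged_with_equal_weight(self):
        table = pd.DataFrame(
            [{"bird_id": "b", "type_label": "t0", "x": v} for v in (95, 100, 105)]
            + [{"bird_id": "b", "type_label": "t1", "x": v} for v in (90, 100, 110)]
        )
        out = feature_cv(table, ["x"], min_renditions=3)
        assert out["cv"].item() == pytest.approx((0.05 + 0.10) / 2)


class TestCffContextRatio:
    def _table(self, uds, ds):
        rows = [{"bird_id": "b", "type_label": "t0", "context": "UDS", "cff_hz": v}
                for v in uds]
        rows += [{"bird_id": "b", "type_label": "t0", "context": "DS", "cff_hz": v}
                 for v in ds]
        return pd.DataFrame(rows)

    def test_hand_computed_ratio(self):
        per_syl, per_bird = cff_context_ratio(
            self._table([98, 100, 102], [99, 100, 101]), min_renditions=3)
        assert per_syl["uds_ds_ratio"].item() == pytest.approx(2.0)
        assert per_bird["uds_ds_ratio"].item() == pytest.approx(2.0)

    def test_identical_contexts_give_ratio_near_one(self):
        template = make_tutor_template(5, seed=3)
        model = PupilModel(template=template,
                           feature_cv={("fundamental_hz", "UDS"): 0.02,
                                       ("fundamental_hz", "DS"): 0.02},
                           ds_variance_scale=1.0, age_schedule={100: 1.0})
        rng = np.random.default_rng(0)
        rows = []
        for ctx in ("UDS", "DS"):
            for _ in range(200):
                rend = generate_rendition(model, ctx, 100, rng)
                rows.append({"bird_id": "b", "type_label": "a", "context": ctx,
                             "cff_hz": rend.syllables[0].fundamental_hz})
        _, per_bird = cff_context_ratio(pd.DataFrame(rows))
        assert per_bird["uds_ds_ratio"].item() == pytest.approx(1.0, abs=0.2)

    def test_syllable_missing_in_one_context_excluded(self):
        table = self._table([98, 100, 102], [])
        with pytest.warns(UserWarning):
            per_syl, per_bird = cff_context_ratio(table, min_renditions=3)
        assert per_syl.empty and per_bird.empty


class TestTrajectory:
    def _summaries(self, multipliers, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for bird in range(6):
            for age, m in multipliers.items():
                rows.append({"bird_id": f"b{bird}", "age_d": age,
                             "cv": 0.1 * m * (1 + rng.normal(0, noise))})
        return pd.DataFrame(rows)

    def test_decreasing_schedule_recovered(self):
        series, trends = developmental_trajectory(
            self._summaries({65: 1.0, 80: 0.7, 100: 0.5}, noise=0.05))
        means = series.sort_values("age_d")["mean"].to_numpy()
        assert (np.diff(means) < 0).all()
        assert trends["slope_sign"].item() == -1
        assert trends["p_value"].item() < 0.01

    def test_flat_schedule_shows_no_trend(self):
        _, trends = developmental_trajectory(
            self._summaries({65: 1.0, 80: 1.0, 100: 1.0}, noise=0.1, seed=3))
        assert trends["p_value"].item() > 0.05

    def test_single_age_trend_undefined_with_warning(self):
        with pytest.warns(UserWarning):
            _, trends = developmental_trajectory(self._summaries({100: 1.0}))
        assert np.isnan(trends["slope"].item())

    def test_cohort_gap_preserved_at_every_age(self):
        a = self._summaries({65: 1.0, 80: 0.7, 100: 0.5}).assign(cohort="a")
        b = a.copy().assign(cohort="b", cv=a["cv"] + 0.05)
        series, _ = developmental_trajectory(pd.concat([a, b]),
                                             group_cols=["cohort"])
        wide = series.pivot(index="age_d", columns="cohort", values="mean")
        assert (wide["b"] - wide["a"] > 0.04).all()


class TestGroupCompare:
    def test_complete_separation_gives_u_zero(self):
        u, p = group_compare([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        # exact two-sided tail: 2 of the C(6,3)=20 orderings are this extreme
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_p_one_with_midranks(self):
        _, p = group_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_paired_t_zero_mean_difference(self):
        t, p = group_compare([2, 2, 2], [1, 2, 3], test="paired_t")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_paired_t_requires_matched_lengths(self):
        with pytest.raises(ValueError):
            group_compare([1, 2], [1, 2, 3], test="paired_t")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            group_compare([1], [2], test="anova")


class TestDeltaDeltaCt:
    def _ct(self, rows):
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])

    def test_worked_example_fold_change_4(self):
        table = self._ct([
            ("s1", "treated", "tgt", 20.0), ("s1", "treated", "ref", 18.0),
            ("s2", "control", "tgt", 22.0), ("s2", "control", "ref", 18.0),
        ])
        res = delta_delta_ct(table, ["tgt"], "ref", "control")
        treated = res.per_sample.set_index("sample")
        assert treated.loc["s1", "ddct"] == pytest.approx(-2.0, abs=1e-12)
        assert treated.loc["s1", "fold"] == pytest.approx(4.0, abs=1e-12)

    def test_identical_groups_fold_1(self):
        table = self._ct([
            ("s1", "treated", "tgt", 21.0), ("s1", "treated", "ref", 18.0),
            ("s2", "control", "tgt", 21.0), ("s2", "control", "ref", 18.0),
        ])
        res = delta_delta_ct(table, ["tgt"], "ref", "control")
        assert np.allclose(res.per_sample["fold"], 1.0)

    def test_triplicates_averaged(self):
        table = self._ct([
            ("s1", "treated", "tgt", 20.0), ("s1", "treated", "tgt", 20.1),
            ("s1", "treated", "tgt", 19.9),
            ("s1", "treated", "ref", 18.0),
            ("s2", "control", "tgt", 21.0), ("s2", "control", "ref", 18.0),
        ])
        res = delta_delta_ct(table, ["tgt"], "ref", "control")
        s1 = res.per_sample.set_index("sample").loc["s1"]
        assert s1["mean_ct"] == pytest.approx(20.0)
        assert s1["replicate_sd"] == pytest.approx(0.1)

    def test_sample_without_reference_excluded_with_warning(self):
        table = self._ct([
            ("s1", "treated", "tgt", 20.0),
            ("s2", "control", "tgt", 21.0), ("s2", "control", "ref", 18.0),
        ])
        with pytest.warns(UserWarning):
            res = delta_delta_ct(table, ["tgt"], "ref", "control")
        assert "s1" not in set(res.per_sample["sample"])
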