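"""Effect-size computation, pooling and heterogeneity statistics.

Pooled estimates are checked against an independent brute-force weighted
mean written in this file, and against statsmodels' meta-analysis
routines as an external oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ablacost.meta import (
    MetaError,
    Z95,
    EffectEstimate,
    StudyRecord,
    effects_from_studies,
    forest_table,
    heterogeneity,
    hr_effect,
    pool_fixed,
    pool_random_dl,
    rr_effect,
    subgroup_pool,
)


def brute_force_fixed(ys, ses):
    """Independent inverse-variance mean: explicit loops, no shortcuts."""
    num = den = 0.0
    for y, s in zip(ys, ses):
        num += y / (s * s)
        den += 1.0 / (s * s)
    return num / den, math.sqrt(1.0 / den)


def estimates(ys, ses, measure="RR"):
    return [
        EffectEstimate(f"s{i}", measure, y, s)
        for i, (y, s) in enumerate(zip(ys, ses))
    ]


class TestRrEffect:
    def test_hand_computed_example(self):
        e = rr_effect(10, 100, 20, 100, cc=0)
        assert e.log_effect == pytest.approx(math.log(0.5), abs=1e-4)
        assert e.se == pytest.approx(math.sqrt(0.13), abs=1e-4)

    def test_identical_arms_null(self):
        assert rr_effect(15, 60, 15, 60, cc=0).log_effect == 0.0

    def test_zero_cell_continuity_correction(self):
        e = rr_effect(0, 50, 5, 50, cc=0.5)
        # corrected cells (0.5, 50.5, 5.5, 50.5)
        expected = math.log((0.5 / 50.5) / (5.5 / 50.5))
        assert e.log_effect == pytest.approx(expected, rel=1e-12)
        assert e.se == pytest.approx(
            math.sqrt(1 / 0.5 - 1 / 50.5 + 1 / 5.5 - 1 / 50.5), rel=1e-12
        )

    def test_no_correction_without_zero_cell(self):
        assert rr_effect(10, 100, 20, 100, cc=0.5) == rr_effect(10, 100, 20, 100, cc=0)

    def test_double_zero_without_correction_is_undefined(self):
        with pytest.raises(MetaError):
            rr_effect(0, 50, 0, 50, cc=0)

    def test_events_above_arm_size_rejected(self):
        with pytest.raises(MetaError):
            rr_effect(70, 60, 10, 60)


class TestHrEffect:
    def test_symmetric_ci_back_calculation(self):
        e = hr_effect(1.0, 0.5, 2.0)
        assert e.log_effect == 0.0
        assert e.se == pytest.approx(math.log(4) / (2 * Z95), rel=1e-9)

    def test_zero_width_ci_rejected(self):
        with pytest.raises(MetaError):
            hr_effect(1.0, 1.0, 1.0)

    def test_published_scale_example(self):
        e = hr_effect(0.96, 0.77, 1.19)
        assert e.log_effect == pytest.approx(-0.0408, abs=1e-4)
        assert e.se == pytest.approx(0.1110, abs=1e-4)

    def test_nonpositive_limits_rejected(self):
        with pytest.raises(MetaError):
            hr_effect(0.96, 0.0, 1.19)


class TestFixedPooling:
    def test_single_study_identity(self):
        e = estimates([0.3], [0.2])
        pooled = pool_fixed(e)
        assert pooled.log_pooled == pytest.approx(0.3)
        assert pooled.se_pooled == pytest.approx(0.2)
        assert pooled.tau2 == 0.0 and pooled.i2 == 0.0

    def test_equal_weight_average(self):
        pooled = pool_fixed(estimates([0.0, 0.6931], [0.5, 0.5]))
        assert pooled.log_pooled == pytest.approx(0.34655, abs=1e-4)
        assert pooled.se_pooled == pytest.approx(0.5 / math.sqrt(2), abs=1e-4)

    def test_empty_and_mixed_measures_rejected(self):
        with pytest.raises(MetaError):
            pool_fixed([])
        mixed = estimates([0.1], [0.2]) + estimates([0.2], [0.2], measure="HR")
        with pytest.raises(MetaError):
            pool_fixed(mixed)

    @given(
        ys=st.lists(st.floats(-2, 2), min_size=1, max_size=8),
        raw_ses=st.lists(st.floats(0.05, 2), min_size=8, max_size=8),
    )
    @settings(max_examples=100, derandomize=True)
    def test_pooled_ratio_within_study_range(self, ys, raw_ses):
        ests = estimates(ys, raw_ses[: len(ys)])
        pooled = pool_fixed(ests)
        ratios = [e.ratio for e in ests]
        assert min(ratios) - 1e-9 <= pooled.ratio <= max(ratios) + 1e-9

    def test_oracle_equivalence_small_k(self):
        ys = [1 / 3, -2 / 7, 5 / 11]
        ses = [1 / 2, 2 / 3, 3 / 5]
        pooled = pool_fixed(estimates(ys, ses))
        y_bf, se_bf = brute_force_fixed(ys, ses)
        assert pooled.log_pooled == pytest.approx(y_bf, abs=1e-12)
        assert pooled.se_pooled == pytest.approx(se_bf, abs=1e-12)

    def test_adding_study_above_mean_raises_mean(self):
        base = estimates([0.0, 0.2], [0.3, 0.4])
        with_extra = base + estimates([1.0], [0.5])
        assert pool_fixed(with_extra).log_pooled > pool_fixed(base).log_pooled


class TestHeterogeneity:
    def test_identical_studies_zero(self):
        q, df, p_q, i2 = heterogeneity(estimates([0.2, 0.2, 0.2], [0.3, 0.3, 0.3]))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert i2 == 0.0
        assert df == 2

    def test_hand_computed_two_studies(self):
        q, df, p_q, i2 = heterogeneity(estimates([0.0, 1.0], [0.5, 0.5]))
        assert q == pytest.approx(2.0, rel=1e-12)
        assert df == 1
        assert i2 == pytest.approx(0.5, rel=1e-12)

    def test_i2_truncates_at_zero_when_q_below_df(self):
        # Nearly identical effects: Q well below df.
        q, df, _, i2 = heterogeneity(
            estimates([0.100, 0.101, 0.099, 0.1], [0.5, 0.5, 0.5, 0.5])
        )
        assert q < df
        assert i2 == 0.0

    def test_requires_two_studies(self):
        with pytest.raises(MetaError):
            heterogeneity(estimates([0.1], [0.2]))


class TestRandomEffects:
    def test_homogeneous_input_collapses_to_fixed(self):
        ests = estimates([0.1, 0.1, 0.1], [0.3, 0.4, 0.5])
        random = pool_random_dl(ests)
        fixed = pool_fixed(ests)
        assert random.tau2 == 0.0
        assert random.log_pooled == pytest.approx(fixed.log_pooled, rel=1e-12)
        assert random.se_pooled == pytest.approx(fixed.se_pooled, rel=1e-12)

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            k = rng.integers(2, 12)
            ests = estimates(rng.normal(0, 0.5, k), rng.uniform(0.1, 0.6, k))
            assert pool_random_dl(ests).se_pooled >= pool_fixed(ests).se_pooled - 1e-12

    def test_requires_two_studies(self):
        with pytest.raises(MetaError, match="fixed"):
            pool_random_dl(estimates([0.1], [0.2]))

    def test_matches_statsmodels_dersimonian_laird(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(11)
        ys = rng.normal(-0.1, 0.4, 9)
        ses = rng.uniform(0.1, 0.5, 9)
        ours = pool_random_dl(estimates(list(ys), list(ses)))
        res = combine_effects(ys, ses**2, method_re="chi2", use_t=False)
        assert ours.tau2 == pytest.approx(res.tau2, rel=1e-8)
        frame = res.summary_frame()
        assert ours.log_pooled == pytest.approx(
            frame.loc["random effect", "eff"], rel=1e-8
        )
        fixed = pool_fixed(estimates(list(ys), list(ses)))
        assert fixed.log_pooled == pytest.approx(
            frame.loc["fixed effect", "eff"], rel=1e-8
        )


class TestSubgroups:
    def test_degenerate_split_equals_full_pool(self):
        ests = [
            EffectEstimate(f"s{i}", "RR", y, 0.3, subgroup="CF")
            for i, y in enumerate([0.1, -0.2, 0.3])
        ]
        res = subgroup_pool(ests)
        assert res["non-CF"] is None
        assert res["CF"]["fixed"].log_pooled == pytest.approx(
            pool_fixed(ests).log_pooled
        )

    def test_unknown_type_excluded_from_split(self):
        labels = ["CF"] * 8 + ["non-CF"] * 6 + ["unknown"] * 4
        ests = [
            EffectEstimate(f"s{i}", "RR", 0.01 * i, 0.3, subgroup=lab)
            for i, lab in enumerate(labels)
        ]
        res = subgroup_pool(ests)
        assert res["CF"]["fixed"].k == 8
        assert res["non-CF"]["fixed"].k == 6


class TestStudyRecords:
    def test_short_followup_excluded(self):
        studies = [
            StudyRecord("a", "RCT", 50, 50, 10, 12, followup_months=12),
            StudyRecord("b", "RCT", 50, 50, 10, 12, followup_months=3),
        ]
        assert len(effects_from_studies(studies, "RR")) == 1

    def test_hr_studies_not_imputed_from_counts(self):
        studies = [StudyRecord("a", "RCT", 50, 50, 10, 12)]
        assert effects_from_studies(studies, "HR") == []

    def test_record_needs_some_measure(self):
        with pytest.raises(MetaError):
            StudyRecord("a", "RCT", 50, 50)

    def test_forest_table_weights_sum_to_100(self):
        ests = estimates([0.1, -0.3, 0.2], [0.2, 0.3, 0.25])
        table = forest_table(ests, pool_fixed(ests))
        assert table["weight_pct"].iloc[:-1].sum() == pytest.approx(100.0)
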