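import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pepticlust.stats import (
    StatsConfig,
    bh_adjust,
    call_direction,
    classify_pattern,
    fold_change,
    frequency_filter,
    rank_sum_batch,
    rm_anova,
    run_differential,
    summarize_regulation,
    wilcoxon_rank_sum,
)


from helpers import brute_force_rank_sum, run_through_matrix


class TestFrequencyFilter:
    @staticmethod
    def make(matrix_rows, group_sizes=(7, 7)):
        n = sum(group_sizes)
        cols = [f"S{i}" for i in range(n)]
        design = pd.DataFrame(
            {
                "sample_id": cols,
                "animal_id": cols,
                "strain": ["A"] * group_sizes[0] + ["B"] * group_sizes[1],
                "time_point": ["NP"] * n,
            }
        )
        return pd.DataFrame(matrix_rows, columns=cols, index=pd.Index(
            range(len(matrix_rows)), name="peptide_id")), design

    def test_boundary_5_of_7_retained_4_of_7_dropped(self):
        row5 = [1] * 5 + [0] * 2 + [0] * 7  # 5/7 in group A = 0.714
        row4 = [1] * 4 + [0] * 3 + [0] * 7  # 4/7 = 0.571
        matrix, design = self.make([row5, row4])
        kept = frequency_filter(matrix, design)
        assert list(kept) == [0]

    def test_fully_detected_always_retained(self):
        matrix, design = self.make([[1] * 14])
        assert list(frequency_filter(matrix, design, StatsConfig(frequency_threshold=1.0))) == [0]

    def test_empty_group_is_an_error(self):
        matrix, design = self.make([[1] * 14])
        design = design.iloc[:7]  # strain B has no samples left
        with pytest.raises(ValueError):
            frequency_filter(matrix.iloc[:, :7], design.iloc[0:0])


class TestWilcoxon:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [4, 5, 6], 0.1),  # 2/20 arrangements as extreme
            ([1, 2], [3, 4], 1 / 3),  # 2/6
            ([1, 2, 3], [1, 2, 3], 1.0),  # identical multisets
            ([5, 5, 5], [5, 5], 1.0),  # all values identical
        ],
    )
    def test_exact_examples(self, a, b, expected):
        assert wilcoxon_rank_sum(a, b) == pytest.approx(expected)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n_a, n_b = rng.integers(2, 8, size=2)
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1))
            a, b = pooled[:n_a], pooled[n_a:]
            ours = wilcoxon_rank_sum(a, b)
            scipy_p = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            assert ours == pytest.approx(scipy_p, abs=1e-12)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n_a, n_b = rng.integers(1, 7, size=2)
            a = rng.integers(0, 4, n_a).astype(float)
            b = rng.integers(0, 4, n_b).astype(float)
            assert wilcoxon_rank_sum(a, b) == pytest.approx(brute_force_rank_sum(a, b))

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=(40, 7))
        b = rng.normal(size=(40, 7))
        batch = rank_sum_batch(a, b)
        singles = [wilcoxon_rank_sum(a[i], b[i]) for i in range(40)]
        assert np.allclose(batch, singles)

    def test_normal_approximation_path_for_large_groups(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 60)
        b = rng.normal(1.0, 1, 60)
        p = wilcoxon_rank_sum(a, b)
        scipy_p = sps.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert p == pytest.approx(scipy_p, rel=0.05)
        assert p < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestBH:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_against_hand_rolled_step_up(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        order = np.argsort(p)
        m = len(p)
        q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), expected)

    def test_lowering_a_p_never_loses_rejections(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.uniform(size=15)
            base = (bh_adjust(p) <= 0.05).sum()
            i = rng.integers(15)
            lowered = p.copy()
            lowered[i] *= rng.uniform()
            assert (bh_adjust(lowered) <= 0.05).sum() >= base

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRMAnova:
    def test_constant_series_gives_p_one(self):
        x = np.tile([3.0, 3.0, 3.0], (4, 1))
        assert rm_anova(x) == 1.0

    def test_pure_subject_offsets_no_time_effect(self):
        x = np.array([[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [9.0, 9.0, 9.0]])
        assert rm_anova(x) == 1.0

    def test_two_timepoints_equal_paired_t_squared(self):
        x = np.array([[2.0, 5.0], [1.0, 4.5], [3.0, 3.5]])
        t_stat, p_t = sps.ttest_rel(x[:, 1], x[:, 0])
        s, t = x.shape
        grand = x.mean()
        ss_time = s * ((x.mean(axis=0) - grand) ** 2).sum()
        ss_err = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2).sum()
        f = (ss_time / 1) / (ss_err / (s - 1))
        assert f == pytest.approx(t_stat**2)
        assert rm_anova(x) == pytest.approx(p_t)

    def test_matches_statsmodels_anovarm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(14)
        x = rng.normal(size=(6, 3)) + np.array([0.0, 0.4, 1.0])
        long = pd.DataFrame(
            {
                "y": x.ravel(),
                "subject": np.repeat(np.arange(6), 3),
                "time": np.tile(np.arange(3), 6),
            }
        )
        res = AnovaRM(long, "y", "subject", within=["time"]).fit()
        expected = float(res.anova_table["Pr > F"].iloc[0])
        assert rm_anova(x) == pytest.approx(expected, rel=1e-9)

    def test_insufficient_subjects_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(np.array([[1.0, 2.0]]))


class TestFoldChangeAndCalls:
    def test_simple_ratio(self):
        fc, flag = fold_change([8, 8], [2, 2])
        assert fc == 4.0 and flag == "ratio"

    def test_a_all_zero_is_down(self):
        fc, flag = fold_change([0, 0], [2, 2])
        assert fc == 0.0 and flag == "ratio"
        assert call_direction(fc, 0.01, StatsConfig()) == "down"

    def test_b_all_zero_is_exclusive(self):
        fc, flag = fold_change([2, 2], [0, 0])
        assert np.isinf(fc) and flag == "exclusive_a"
        assert call_direction(fc, 0.01, StatsConfig()) == "up"

    def test_both_zero_undefined(self):
        fc, flag = fold_change([0.0], [0.0])
        assert np.isnan(fc) and flag == "undefined"
        assert call_direction(fc, 0.01, StatsConfig()) == "none"

    @pytest.mark.parametrize(
        "fc,q,expected",
        [
            (1.5, 0.04, "up"),  # admitted exactly at the cutoff
            (1.4, 0.01, "none"),  # below the 1.5-fold cutoff
            (1 / 1.5, 0.04, "down"),
            (2.0, 0.2, "none"),  # not significant
        ],
    )
    def test_regulation_boundaries(self, fc, q, expected):
        assert call_direction(fc, q, StatsConfig()) == expected


class TestPatternClassification:
    @pytest.mark.parametrize(
        "flags,pattern,retained",
        [
            ((True, True, True), "all_timepoints", True),
            ((False, True, True), "GD12_and_GD18", True),
            ((False, True, False), "single_timepoint", False),
            ((True, False, False), "single_timepoint", False),
            ((True, True, False), "none", False),
            ((True, False, True), "none", False),
            ((False, False, False), "none", False),
        ],
    )
    def test_patterns(self, flags, pattern, retained):
        assert classify_pattern(*flags) == (pattern, retained)


class TestStudyLevel:
    def test_paper_like_noiseless_study_flags_umod(
        self, noiseless_paper_study, default_study
    ):
        matrix, summary = run_through_matrix(noiseless_paper_study)
        res = run_differential(
            matrix, noiseless_paper_study.design, hypertensive="SHRSP"
        )
        # Umod clusters are up 4x/8x at GD12/GD18 only: pattern GD12_and_GD18
        assert (res.patterns.pattern == "GD12_and_GD18").sum() >= 7
        reg = summarize_regulation(res)
        up = reg[(reg.pattern == "GD12_and_GD18") & (reg.direction == "up")]
        assert not up.empty and int(up["count"].iloc[0]) >= 7

    def test_null_noiseless_study_flags_nothing(self, noiseless_null_study):
        matrix, _ = run_through_matrix(noiseless_null_study)
        res = run_differential(matrix, noiseless_null_study.design, hypertensive="SHRSP")
        assert not res.patterns.retained_for_analysis.any()
        assert (res.patterns.pattern == "none").all()

    def test_null_rejection_rate_is_conservative(self):
        """Exact discrete test: raw rejection rate ≤ nominal 0.05, near the
        attainable size of the 7v7 rank-sum test (≈0.038) on tie-free rows."""
        from pepticlust import synthetic
        rates = []
        for seed in range(6):
            study = synthetic.generate_study(
                synthetic.StudyConfig(seed=1000 + seed, scenario="null")
            )
            matrix, _ = run_through_matrix(study)
            res = run_differential(matrix, study.design, hypertensive="SHRSP")
            for tab in res.per_comparison.values():
                rates.append((tab.p_value < 0.05).mean())
        assert 0.01 < np.mean(rates) <= 0.055

    def test_summarize_regulation_empty(self, noiseless_null_study):
        matrix, _ = run_through_matrix(noiseless_null_study)
        res = run_differential(matrix, noiseless_null_study.design, hypertensive="SHRSP")
        reg = summarize_regulation(res)
        assert set(reg.direction) <= {"none"}
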