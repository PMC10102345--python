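"""Statistical tests against closed-form oracles and scipy cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dtialps import (
    GroupSummary,
    adjust_pvalues,
    chi_square_2x2,
    paired_t,
    pearson_partial,
    spearman,
    two_sample_t,
)
from dtialps.stats import welch_replicates


def _pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


def _partial_recursive(x, y, z, w=None):
    """First/second-order partial correlation by the recursion formula."""

    def first_order(a, b, c):
        rab, rac, rbc = _pearson(a, b), _pearson(a, c), _pearson(b, c)
        return (rab - rac * rbc) / np.sqrt((1 - rac**2) * (1 - rbc**2))

    if w is None:
        return first_order(x, y, z)
    rxy_z = first_order(x, y, z)
    rxw_z = first_order(x, w, z)
    ryw_z = first_order(y, w, z)
    return (rxy_z - rxw_z * ryw_z) / np.sqrt((1 - rxw_z**2) * (1 - ryw_z**2))


class TestTwoSampleT:
    def test_welch_from_printed_alps_summaries(self):
        res = two_sample_t((1.424, 0.132, 20), (1.565, 0.197, 30), "welch")
        assert res.statistic == pytest.approx(-3.03, abs=0.01)
        assert res.p_value < 0.01

    def test_welch_from_printed_age_summaries(self):
        res = two_sample_t((59.2, 12.1, 20), (54.6, 7.4, 30), "welch")
        assert res.statistic == pytest.approx(1.52, abs=0.01)

    def test_identical_groups_give_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, x)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_summary_and_sample_paths_agree_exactly(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1.3, 25)
        for variant in ("welch", "student"):
            from_samples = two_sample_t(a, b, variant)
            from_summaries = two_sample_t(
                GroupSummary.from_sample(a), GroupSummary.from_sample(b), variant
            )
            assert from_samples.statistic == from_summaries.statistic
            assert from_samples.p_value == from_summaries.p_value

    def test_matches_scipy(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 2, 18)
        res_w = two_sample_t(a, b, "welch")
        sp_w = sps.ttest_ind(a, b, equal_var=False)
        assert res_w.statistic == pytest.approx(sp_w.statistic, rel=1e-12)
        assert res_w.p_value == pytest.approx(sp_w.pvalue, rel=1e-9)
        res_s = two_sample_t(a, b, "student")
        sp_s = sps.ttest_ind(a, b, equal_var=True)
        assert res_s.statistic == pytest.approx(sp_s.statistic, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_welch_df_between_bounds(self):
        res = two_sample_t((1.0, 0.5, 10), (2.0, 2.0, 40), "welch")
        assert min(10, 40) - 1 <= res.df <= 10 + 40 - 2


class TestPairedT:
    def test_hand_computed_example(self):
        # differences (0.1, 0.2, 0.3): mean 0.2, sd 0.1 -> t = 0.2/(0.1/sqrt 3)
        res = paired_t([1.1, 1.2, 1.3], [1.0, 1.0, 1.0])
        assert res.statistic == pytest.approx(0.2 / (0.1 / np.sqrt(3)), rel=1e-9)
        assert res.df == 2

    def test_identical_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_antisymmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=14), rng.normal(0.3, 1, 14)
        res = paired_t(x, y)
        sp = sps.ttest_rel(x, y)
        assert res.statistic == pytest.approx(sp.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(sp.pvalue, rel=1e-9)


class TestChiSquare:
    def test_yates_on_sex_counts(self):
        res = chi_square_2x2([[16, 4], [20, 10]], yates=True)
        assert res.statistic == pytest.approx(0.50, abs=0.005)
        assert res.p_value == pytest.approx(0.479, abs=0.005)

    def test_plain_pearson_formula(self):
        res = chi_square_2x2([[16, 4], [20, 10]], yates=False)
        # N(ad-bc)^2 / (r1 r2 c1 c2)
        expected = 50 * (16 * 10 - 4 * 20) ** 2 / (20 * 30 * 36 * 14)
        assert res.statistic == pytest.approx(expected, rel=1e-9)

    def test_proportional_table_zero(self):
        res = chi_square_2x2([[10, 10], [20, 20]], yates=False)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -x).statistic == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 3.0, 3.0, 4.0, 5.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 4.0, 7.0, 6.0, 6.0])

        def midranks(v):
            order = np.argsort(v, kind="mergesort")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        oracle = _pearson(midranks(x), midranks(y))
        assert spearman(x, y).statistic == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson_partial(x, y)
        assert res.statistic == pytest.approx(_pearson(x, y), abs=1e-12)
        assert res.df == 18

    def test_residual_identity(self):
        rng = np.random.default_rng(13)
        z = rng.normal(size=25)
        x = rng.normal(size=25)
        y = x + 3.0 * z - 1.0  # y is x plus a covariate-explained part
        res = pearson_partial(x, y, [z])
        assert res.statistic == pytest.approx(1.0, abs=1e-10)

    def test_matches_recursive_oracle_two_covariates(self):
        """Residual method equals the recursion formula on 20-subject tables."""
        rng = np.random.default_rng(14)
        for _ in range(10):
            x, y = rng.normal(size=20), rng.normal(size=20)
            z, w = rng.normal(size=20), rng.normal(size=20)
            res = pearson_partial(x, y, [z, w])
            assert res.statistic == pytest.approx(
                _partial_recursive(x, y, z, w), abs=1e-10
            )
            assert res.df == 16

    def test_affine_invariance_of_covariates(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=30), rng.normal(size=30)
        z, w = rng.normal(size=30), rng.normal(size=30)
        base = pearson_partial(x, y, [z, w])
        shifted = pearson_partial(x, y, [5.0 * z - 2.0, -0.3 * w + 7.0])
        assert shifted.statistic == pytest.approx(base.statistic, abs=1e-12)
        assert shifted.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(16)
        x, y, z = rng.normal(size=20), rng.normal(size=20), rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            pearson_partial(x, y, [z, 2.0 * z])

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n >"):
            pearson_partial([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [[0.0, 1.0, 0.0]])


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03], "bonferroni"), [0.03])

    def test_bonferroni_multiplies_and_caps(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bonferroni"), [0.03, 0.06, 0.09]
        )
        assert adjust_pvalues([0.9, 0.8], "bonferroni").max() == 1.0

    def test_bh_monotone_and_bounded(self):
        rng = np.random.default_rng(18)
        p = rng.uniform(size=30)
        adj = adjust_pvalues(p, "bh")
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


class TestWelchReplicates:
    def test_deterministic(self):
        a = GroupSummary(1.0, 0.2, 20)
        b = GroupSummary(1.0, 0.3, 30)
        t1, p1 = welch_replicates(a, b, 100, seed=5)
        t2, p2 = welch_replicates(a, b, 100, seed=5)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(p1, p2)

    @settings(deadline=None, derandomize=True, max_examples=10)
    @given(st.integers(0, 10**6))
    def test_single_replicate_matches_two_sample_t(self, seed):
        a = GroupSummary(1.4, 0.15, 12)
        b = GroupSummary(1.5, 0.2, 15)
        t, p = welch_replicates(a, b, 1, seed=seed)
        rng = np.random.default_rng(seed)
        xa = rng.normal(a.mean, a.sd, a.n)
        xb = rng.normal(b.mean, b.sd, b.n)
        res = two_sample_t(xa, xb, "welch")
        assert t[0] == pytest.approx(res.statistic, rel=1e-12)
        assert p[0] == pytest.approx(res.p_value, rel=1e-9)
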