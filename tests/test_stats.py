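"""Group summaries, t-tests (pooled/Welch/summary-only) and Mann-Whitney U."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy import stats as sps

from strokevol import (
    compare_cohort,
    mann_whitney_u,
    summarize,
    t_test,
    t_test_from_summary,
)
from strokevol.stats import comparisons_to_table, format_report


class TestSummarize:
    def test_small_example(self):
        s = summarize([1.0, 2.0, 3.0], "g")
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)
        assert s.n == 3

    def test_constant_list_zero_sd(self):
        assert summarize([4.2] * 5).sd == 0.0

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(1)
        values = rng.normal(10.0, 3.0, 8)
        s = summarize(values)
        mean = sum(values) / 8.0
        sd = math.sqrt(sum((v - mean) ** 2 for v in values) / 7.0)
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0])


class TestTTestFromSummary:
    def test_identical_summaries(self):
        r = t_test_from_summary(5.0, 1.0, 8, 5.0, 1.0, 8)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_two_sided == pytest.approx(1.0)
        assert not r.significant

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_large_separation_is_significant(self, variant):
        r = t_test_from_summary(27.1, 11.1, 8, 14.3, 7.2, 8, variant=variant)
        assert r.p_two_sided < 0.05
        assert r.significant

    def test_pooled_matches_quadrature_oracle(self):
        r = t_test_from_summary(12.0, 4.0, 8, 9.0, 5.0, 8, variant="pooled")
        # two-sided p by numerical integration of the t density
        tail, _ = integrate.quad(lambda x: sps.t.pdf(x, r.df), abs(r.statistic), np.inf)
        assert r.p_two_sided == pytest.approx(2.0 * tail, rel=1e-8)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_matches_scipy_from_stats(self, variant):
        rng = np.random.default_rng(2)
        for _ in range(20):
            m1, m2 = rng.normal(0, 5, 2)
            sd1, sd2 = rng.uniform(0.5, 4.0, 2)
            n1, n2 = rng.integers(3, 15, 2)
            mine = t_test_from_summary(m1, sd1, int(n1), m2, sd2, int(n2), variant)
            ref = sps.ttest_ind_from_stats(
                m1, sd1, n1, m2, sd2, n2, equal_var=(variant == "pooled")
            )
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_zero_variance(self):
        equal = t_test_from_summary(3.0, 0.0, 4, 3.0, 0.0, 4)
        assert equal.p_two_sided == 1.0
        different = t_test_from_summary(3.0, 0.0, 4, 4.0, 0.0, 4)
        assert different.p_two_sided == 0.0

    def test_pooled_equals_welch_for_balanced_equal_sd(self):
        a = t_test_from_summary(10.0, 2.5, 8, 8.0, 2.5, 8, "pooled")
        b = t_test_from_summary(10.0, 2.5, 8, 8.0, 2.5, 8, "welch")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
        assert a.df == pytest.approx(b.df, abs=1e-9)


class TestTTest:
    def test_identical_lists(self):
        v = [1.0, 2.0, 3.0, 4.0]
        assert t_test(v, v).p_two_sided == pytest.approx(1.0)

    def test_equals_summary_composition(self):
        rng = np.random.default_rng(3)
        v1, v2 = rng.normal(0, 1, 8), rng.normal(0.7, 1.3, 8)
        direct = t_test(v1, v2, "welch")
        s1, s2 = summarize(v1), summarize(v2)
        composed = t_test_from_summary(s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, "welch")
        assert direct.statistic == composed.statistic
        assert direct.p_two_sided == composed.p_two_sided

    def test_shifting_one_group_increases_t(self):
        rng = np.random.default_rng(4)
        v1, v2 = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        base = abs(t_test(v1, v2).statistic)
        shifted = abs(t_test(v1, np.asarray(v2) + 2.0).statistic)
        assert shifted > base

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        shift=st.floats(min_value=-50.0, max_value=50.0),
        scale=st.floats(min_value=0.01, max_value=100.0),
    )
    def test_invariance_under_affine_rescaling(self, shift, scale):
        rng = np.random.default_rng(5)
        v1, v2 = rng.normal(0, 1, 8), rng.normal(0.8, 1.2, 8)
        base = t_test(v1, v2)
        moved = t_test(scale * v1 + shift, scale * v2 + shift)
        assert moved.p_two_sided == pytest.approx(base.p_two_sided, abs=1e-12)


def _brute_force_exact_p(v1, v2):
    """Independent enumeration of U over all rank assignments."""
    pooled = np.concatenate([v1, v2])
    ranks = sps.rankdata(pooled)
    n1, n = len(v1), len(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    us = [
        sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        for combo in itertools.combinations(range(n), n1)
    ]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMannWhitney:
    def test_fully_separated_pairs(self):
        r = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert r.statistic == 0.0
        assert r.p_two_sided == pytest.approx(2.0 / 6.0)

    def test_symmetric_input_p_one(self):
        r = mann_whitney_u([1.0, 4.0], [2.0, 3.0], method="exact")
        assert r.p_two_sided == pytest.approx(1.0)

    def test_exact_matches_enumeration_all_small_shapes(self):
        rng = np.random.default_rng(6)
        for n1 in range(1, 9):
            for n2 in range(n1, 11 - n1):
                v1 = rng.normal(0.0, 1.0, n1)
                v2 = rng.normal(0.5, 1.0, n2)
                mine = mann_whitney_u(v1, v2, method="exact")
                assert mine.p_two_sided == pytest.approx(
                    _brute_force_exact_p(v1, v2), abs=1e-12
                )

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(7)
        v1, v2 = rng.normal(0, 1, 5), rng.normal(1.0, 1, 6)
        mine = mann_whitney_u(v1, v2, method="exact")
        ref = sps.mannwhitneyu(v1, v2, method="exact")
        assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approximation_close_to_exact_at_n8(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            v1, v2 = rng.normal(0, 1, 8), rng.normal(0.8, 1, 8)
            exact = mann_whitney_u(v1, v2, method="exact").p_two_sided
            approx = mann_whitney_u(v1, v2, method="asymptotic").p_two_sided
            assert abs(exact - approx) < 0.02

    def test_auto_switches_on_sample_size_and_ties(self):
        tied = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])  # ties: asymptotic
        ref = sps.mannwhitneyu([1.0, 2.0, 2.0], [2.0, 3.0, 4.0], method="asymptotic")
        assert tied.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCompareCohort:
    @staticmethod
    def _table(rng=None, delta=0.0):
        rng = rng or np.random.default_rng(9)
        rows = []
        for g, mu in (("treatment", delta), ("control", 0.0)):
            for i in range(8):
                rows.append({"animal_id": f"{g}{i}", "group": g,
                             "lesion": rng.normal(mu, 1.0), "mls": rng.normal(0.3, 0.1)})
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        df = self._table()
        df["lesion"] = list(range(8)) + list(range(8))
        results = compare_cohort(df, ["lesion"], test_plan={"lesion": ["t_pooled"]})
        assert results[0].p_two_sided == pytest.approx(1.0)

    def test_single_endpoint_passthrough(self):
        df = self._table(delta=1.5)
        res = compare_cohort(df, ["lesion"], test_plan={"lesion": ["t_pooled"]})[0]
        v1 = df[df.group == "treatment"]["lesion"].to_numpy()
        v2 = df[df.group == "control"]["lesion"].to_numpy()
        direct = t_test(v1, v2, "pooled", endpoint="lesion")
        assert res.statistic == direct.statistic
        assert res.p_two_sided == direct.p_two_sided

    def test_plan_selects_mann_whitney(self):
        df = self._table()
        res = compare_cohort(df, ["mls"], test_plan={"mls": ["mann_whitney"]})
        assert res[0].test == "mann_whitney"

    def test_missing_endpoint_rejected(self):
        with pytest.raises(KeyError):
            compare_cohort(self._table(), ["volume"])

    def test_table_and_report_rendering(self):
        results = compare_cohort(self._table(delta=2.0), ["lesion", "mls"])
        table = comparisons_to_table(results)
        assert set(table.columns) >= {"endpoint", "test", "p_two_sided", "significant"}
        assert "lesion" in format_report(results)
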