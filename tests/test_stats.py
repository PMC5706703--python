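"""Rank statistics: exact Wilcoxon, Bonferroni, Scheirer-Ray-Hare."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from candycatch.stats import (
    bonferroni,
    group_performance_test,
    performance_vs_chance,
    scheirer_ray_hare,
    slopes_factorial_test,
    wilcoxon_signed_rank,
)


def brute_force_signed_rank_p(diffs, alternative):
    """Literal enumeration of all 2^m sign assignments on the observed ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    t_minus = ranks[d < 0].sum()
    m = len(d)
    sums = np.array(
        [np.dot(signs, ranks) for signs in itertools.product([0, 1], repeat=m)]
    )
    p_le = np.mean(sums <= t_minus + 1e-9)
    p_ge = np.mean(sums >= t_minus - 1e-9)
    if alternative == "greater":
        return p_le
    if alternative == "less":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_differences(self):
        d = np.arange(1, 10, dtype=float)  # 9 positive differences
        res = wilcoxon_signed_rank(d, alternative="greater", mode="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0 / 512.0, abs=1e-12)
        two = wilcoxon_signed_rank(d, alternative="two-sided", mode="exact")
        assert two.statistic == 0.0
        assert two.p_value == pytest.approx(2.0 / 512.0, abs=1e-12)

    def test_antisymmetric_pair_is_null(self):
        res = wilcoxon_signed_rank([0.3, -0.3], mode="exact")
        assert res.p_value == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_brute_force_enumeration(self, rng, alternative):
        for trial in range(8):
            m = int(rng.integers(3, 13))
            d = np.round(rng.normal(0.1, 1.0, m), 1)  # rounding induces ties
            d = d[d != 0]
            if d.size == 0:
                continue
            ours = wilcoxon_signed_rank(d, alternative=alternative, mode="exact")
            expected = brute_force_signed_rank_p(d, alternative)
            assert ours.p_value == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(10):
            d = rng.normal(0.2, 1.0, 12)
            for alt in ("two-sided", "greater", "less"):
                ours = wilcoxon_signed_rank(d, alternative=alt, mode="exact")
                ref = sps.wilcoxon(d, alternative=alt, method="exact")
                assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_normal_agree_at_m20(self, rng):
        for _ in range(10):
            d = rng.normal(0.2, 1.0, 20)
            for alt in ("two-sided", "greater"):
                pe = wilcoxon_signed_rank(d, alternative=alt, mode="exact").p_value
                pa = wilcoxon_signed_rank(d, alternative=alt, mode="approx").p_value
                assert pa == pytest.approx(pe, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_signed_rank([])


class TestBonferroni:
    def test_examples(self):
        assert bonferroni([0.00195, 0.00195]) == pytest.approx([0.0039, 0.0039])
        assert bonferroni([0.7, 0.9]) == [1.0, 1.0]
        assert bonferroni([0.2]) == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        adj = bonferroni(ps)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))


def brute_force_srh_two_way(df):
    """SRH on a balanced two-way layout via direct group-mean SS formulas."""
    r = sps.rankdata(df["y"])
    df = df.assign(r=r)
    grand = r.mean()
    ss_tot = ((r - grand) ** 2).sum()
    ms = ss_tot / (len(df) - 1)
    mean_a = df.groupby("a")["r"].mean()
    mean_b = df.groupby("b")["r"].mean()
    mean_ab = df.groupby(["a", "b"])["r"].mean()
    n_a = df.groupby("a").size()
    n_b = df.groupby("b").size()
    n_ab = df.groupby(["a", "b"]).size()
    ss_a = (n_a * (mean_a - grand) ** 2).sum()
    ss_b = (n_b * (mean_b - grand) ** 2).sum()
    ss_ab = sum(
        n_ab[key] * (mean_ab[key] - mean_a[key[0]] - mean_b[key[1]] + grand) ** 2
        for key in mean_ab.index
    )
    return {"a": ss_a / ms, "b": ss_b / ms, "a:b": ss_ab / ms}


class TestScheirerRayHare:
    def test_single_factor_equals_kruskal_wallis(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 5))
            groups = [np.round(rng.normal(i * 0.3, 1.0, rng.integers(4, 9)), 1)
                      for i in range(k)]
            df = pd.DataFrame(
                {
                    "y": np.concatenate(groups),
                    "g": np.concatenate(
                        [np.full(len(g), f"g{i}") for i, g in enumerate(groups)]
                    ),
                }
            )
            res = scheirer_ray_hare(df, "y", ["g"])[0]
            ref = sps.kruskal(*groups)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_two_way_matches_brute_force(self, rng):
        for _ in range(10):
            rows = []
            for a in "xy":
                for b in "pqr":
                    for _rep in range(4):
                        rows.append({"a": a, "b": b, "y": round(rng.normal(), 1)})
            df = pd.DataFrame(rows)
            expected = brute_force_srh_two_way(df)
            got = {
                r.name.removeprefix("SRH "): r.statistic
                for r in scheirer_ray_hare(df, "y", ["a", "b"])
            }
            for eff in expected:
                assert got[eff] == pytest.approx(expected[eff], abs=1e-8)

    def test_shift_and_monotone_transform_invariance(self, rng):
        rows = []
        for a in "xy":
            for b in "pq":
                for _rep in range(5):
                    rows.append({"a": a, "b": b, "y": rng.normal()})
        df = pd.DataFrame(rows)
        base = [r.statistic for r in scheirer_ray_hare(df, "y", ["a", "b"])]
        shifted = df.assign(y=df.y + 5.0)
        cubed = df.assign(y=df.y**3)  # strictly increasing transform
        for other in (shifted, cubed):
            stats = [r.statistic for r in scheirer_ray_hare(other, "y", ["a", "b"])]
            assert stats == pytest.approx(base, abs=1e-10)

    def test_three_way_layout_dfs(self, cohort_slopes):
        results = slopes_factorial_test(cohort_slopes)
        by_name = {r.name: r for r in results}
        assert by_name["SRH group"].df == 1
        assert by_name["SRH prior_label"].df == 1
        assert by_name["SRH likelihood_label"].df == 2
        assert by_name["SRH group:prior_label:likelihood_label"].df == 2
        assert all(0 <= r.p_value <= 1 for r in results)
        # the simulated cohort has strong prior and likelihood effects
        assert by_name["SRH prior_label"].p_value < 0.01
        assert by_name["SRH likelihood_label"].p_value < 0.001

    def test_empty_cell_named(self):
        df = pd.DataFrame(
            {"a": ["x", "x", "y"], "b": ["p", "q", "p"], "y": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="a=y, b=q"):
            scheirer_ray_hare(df, "y", ["a", "b"])

    def test_effect_selection(self, cohort_slopes):
        only = slopes_factorial_test(cohort_slopes, effects=["group"])
        assert len(only) == 1 and only[0].name == "SRH group"
        with pytest.raises(ValueError, match="unknown effects"):
            slopes_factorial_test(cohort_slopes, effects=["nope"])


class TestPower:
    def test_group_effect_detects_weight_difference(self):
        # groups whose mean reliance weights differ by 0.2 (motor noise 0.05,
        # 9 subjects per group) should be detected in most simulations
        from candycatch.experiments import power_experiment

        res = power_experiment(seed=4000, n_sims=25)
        assert res["rejection_rate"] > 0.5


class TestStudyWrappers:
    def test_performance_vs_chance_bonferroni(self, cohort, design):
        from candycatch.estimation import cohort_performance

        perf = cohort_performance(cohort, design)
        results = performance_vs_chance(perf, chance=0.02)
        assert len(results) == 2
        for r in results:
            # every simulated subject performs far above 2%: W = 0
            assert r.statistic == 0.0
            assert r.p_adjusted == pytest.approx(min(1.0, 2 * r.p_value))
            assert r.p_adjusted < 0.05

    def test_group_test_paired_and_unpaired(self, cohort, design):
        from candycatch.estimation import cohort_performance

        perf = cohort_performance(cohort, design)
        paired = group_performance_test(perf, paired=True)
        unpaired = group_performance_test(perf, paired=False)
        assert 0 <= paired.p_value <= 1
        assert 0 <= unpaired.p_value <= 1
        assert "Mann-Whitney" in unpaired.name

    def test_group_test_requires_two_groups(self):
        perf = pd.DataFrame(
            {"group": ["TD"] * 4, "age": range(4), "p_correct": [0.1] * 4}
        )
        with pytest.raises(ValueError, match="2 groups"):
            group_performance_test(perf)
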