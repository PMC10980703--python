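"""Paired-cohort statistics against closed-form and reference oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from mitoburden.cohort_stats import (
    ComparisonResult,
    StatsError,
    apply_fdr,
    bh_fdr,
    covariate_checks,
    discordant_prevalence,
    dupont_paired_power,
    fisher_montecarlo,
    kruskal_by_group,
    mcnemar_exact,
    one_sample_t,
    paired_t,
    two_sample_t,
)


class TestDiscordantPrevalence:
    def test_pilot_counts(self):
        """9/2 discordant pairs of 20 give 45% and 10% discordant prevalence."""
        a = [True] * 11 + [False] * 9
        b = [True] * 2 + [False] * 9 + [True] * 2 + [False] * 7
        d = discordant_prevalence(a, b)
        assert (d.b, d.c) == (9, 2)
        assert d.prevalence_a == pytest.approx(0.45)
        assert d.prevalence_b == pytest.approx(0.10)

    def test_concordant_pairs(self):
        d = discordant_prevalence([True, False], [True, False])
        assert (d.b, d.c) == (0, 0)

    def test_swapping_members_swaps_counts(self, rng):
        a = rng.random(30) < 0.5
        b = rng.random(30) < 0.5
        d1 = discordant_prevalence(a, b)
        d2 = discordant_prevalence(b, a)
        assert (d1.b, d1.c) == (d2.c, d2.b)
        assert d1.b + d1.c + int((a == b).sum()) == 30

    def test_empty_pairs_rejected(self):
        with pytest.raises(StatsError):
            discordant_prevalence([], [])


class TestMcNemar:
    def test_exact_closed_form(self):
        # two-sided exact: 2 * sum_{k>=9} C(11,k) / 2^11
        expected = 2 * sum(math.comb(11, k) for k in range(9, 12)) / 2**11
        assert mcnemar_exact(9, 2) == pytest.approx(expected)
        assert mcnemar_exact(9, 2) == pytest.approx(0.0654296875)

    @pytest.mark.parametrize("b, c", [(5, 5), (0, 0)])
    def test_symmetric_and_degenerate(self, b, c):
        assert mcnemar_exact(b, c) == 1.0

    def test_matches_reference_exact(self, rng):
        for _ in range(100):
            b, c = int(rng.integers(0, 13)), int(rng.integers(0, 13))
            if b + c == 0:
                continue
            ref = sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(ref, abs=1e-12)

    def test_asymptotic_branch_matches_reference(self, rng):
        for _ in range(50):
            b, c = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            if b + c < 25:
                continue
            ref = sm_mcnemar([[0, b], [c, 0]], exact=False, correction=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(ref, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(StatsError):
            mcnemar_exact(-1, 2)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.5]) == pytest.approx([0.5])

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 30)))
            q = bh_fdr(p)
            assert (q >= p - 1e-15).all() and (q <= 1.0).all()
            # independent step-up oracle
            order = np.argsort(p)
            m = len(p)
            stepped = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert q == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_fdr([0.5, 1.2])

    def test_apply_fdr_groups_by_family(self):
        results = [
            ComparisonResult("f1", "u1", "t", 0.0, 0.01, 0.0, 5),
            ComparisonResult("f1", "u2", "t", 0.0, 0.04, 0.0, 5),
            ComparisonResult("f2", "u3", "t", 0.0, 0.04, 0.0, 5),
        ]
        out = apply_fdr(results)
        assert out[0].p_fdr == pytest.approx(0.02)
        assert out[2].p_fdr == pytest.approx(0.04)  # own family of one


class TestTTests:
    def test_paired_t_closed_form(self, rng):
        """Matches the textbook t = d̄ / (s_d/√n) with Student-t tail."""
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a = rng.normal(0, 1, n)
            b = rng.normal(0.2, 1, n)
            res = paired_t(a, b, "f", "u")
            d = a - b
            t = d.mean() / (d.std(ddof=1) / math.sqrt(n))
            p = 2 * stats.t.sf(abs(t), n - 1)
            assert res.statistic == pytest.approx(t, abs=1e-10)
            assert res.p_raw == pytest.approx(p, abs=1e-10)

    def test_identical_vectors_degenerate(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "f", "u")
        assert res.p_raw == 1.0 and res.effect == 0.0 and res.note == "degenerate"

    def test_uniform_shift_recovers_effect(self):
        res = paired_t([1.1, 2.4, 3.0], [1.0, 2.3, 2.9], "f", "u")
        assert res.effect == pytest.approx(0.1)

    def test_one_and_two_sample_match_reference(self, rng):
        for _ in range(100):
            x = rng.normal(0.1, 1, int(rng.integers(3, 30)))
            y = rng.normal(0.0, 1, int(rng.integers(3, 30)))
            r1 = one_sample_t(x, "f", "u")
            t1, p1 = stats.ttest_1samp(x, 0.0)
            assert (r1.statistic, r1.p_raw) == pytest.approx((t1, p1), abs=1e-10)
            r2 = two_sample_t(x, y, "f", "u")
            t2, p2 = stats.ttest_ind(x, y)
            assert (r2.statistic, r2.p_raw) == pytest.approx((t2, p2), abs=1e-10)

    def test_too_few_pairs_not_testable(self):
        assert not paired_t([1.0], [2.0], "f", "u").testable


class TestKruskal:
    def test_matches_hand_coded_midrank_statistic(self, rng):
        for _ in range(100):
            groups = rng.integers(0, 3, size=40)
            values = rng.integers(0, 6, size=40).astype(float)  # heavy ties
            res = kruskal_by_group(values, groups, "f", "u", min_per_group=3)
            ranks = stats.rankdata(values)
            n = len(values)
            h = 12 / (n * (n + 1)) * sum(
                ranks[groups == g].sum() ** 2 / (groups == g).sum()
                for g in np.unique(groups)) - 3 * (n + 1)
            _, counts = np.unique(values, return_counts=True)
            tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
            h /= tie
            k = len(np.unique(groups))
            assert res.statistic == pytest.approx(h, abs=1e-10)
            assert res.p_raw == pytest.approx(stats.chi2.sf(h, k - 1), abs=1e-10)

    def test_identical_distributions_near_null(self):
        res = kruskal_by_group([1, 1, 1, 1, 1, 1], list("aaabbb"), "f", "u")
        assert res.p_raw == 1.0

    def test_small_groups_dropped(self):
        res = kruskal_by_group([1, 2, 3, 4, 9], list("aaab") + ["b"], "f", "u",
                               min_per_group=3)
        assert not res.testable  # only one group of ≥3 remains

    def test_permutation_reference_agrees_on_well_behaved_data(self, rng):
        values = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.0, 1, 40)])
        groups = np.repeat(["a", "b"], 40)
        asym = kruskal_by_group(values, groups, "f", "u")
        perm = kruskal_by_group(values, groups, "f", "u", n_perm=20_000,
                                rng=np.random.default_rng(5))
        assert perm.test_name == "kruskal_wallis_perm"
        assert perm.statistic == pytest.approx(asym.statistic)
        assert perm.p_raw == pytest.approx(asym.p_raw, abs=0.01)

    def test_permutation_reference_is_seeded(self, rng):
        values = rng.normal(0, 1, 30)
        groups = np.repeat(["a", "b", "c"], 10)
        p1 = kruskal_by_group(values, groups, "f", "u", n_perm=2000,
                              rng=np.random.default_rng(9)).p_raw
        p2 = kruskal_by_group(values, groups, "f", "u", n_perm=2000,
                              rng=np.random.default_rng(9)).p_raw
        assert p1 == p2


class TestFisherMonteCarlo:
    def test_perfect_independence(self):
        p = fisher_montecarlo([[10, 10], [10, 10]], n_sim=5000, seed=1)
        assert p > 0.5

    def test_matches_exact_fisher_2x2(self):
        table = [[12, 3], [4, 13]]
        exact = stats.fisher_exact(table)[1]
        p = fisher_montecarlo(table, n_sim=100_000, seed=2)
        assert p == pytest.approx(exact, abs=0.01)

    def test_seed_determinism(self):
        t = [[8, 2], [3, 9]]
        assert fisher_montecarlo(t, 2000, seed=7) == fisher_montecarlo(t, 2000, seed=7)

    def test_diagonal_table_small_p(self):
        assert fisher_montecarlo([[10, 0], [0, 10]], n_sim=100_000, seed=3) < 0.001

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            fisher_montecarlo([[0, 0], [5, 5]], 2000, seed=1)


class TestCovariateChecks:
    def test_perfect_age_correlation_kendall(self):
        age = pd.Series(np.arange(20.0, 40.0))
        metric = age * 2 + 1
        sex = pd.Series(["F", "M"] * 10)
        out = covariate_checks(metric, age, sex, count_metric=True)
        kendall = next(r for r in out if r.test_name == "kendall_tau")
        assert kendall.statistic == pytest.approx(1.0)

    def test_balanced_sexes_identical_distributions(self, rng):
        n = 200
        sex = pd.Series(["F"] * (n // 2) + ["M"] * (n // 2))
        metric = pd.Series(np.tile(rng.normal(0, 1, n // 2), 2))
        carrier = pd.Series([True, False] * (n // 2))
        out = covariate_checks(metric, pd.Series(rng.uniform(20, 50, n)), sex,
                               carrier=carrier)
        z = next(r for r in out if r.test_name == "two_proportion_z")
        assert z.p_raw > 0.9  # carrier rate identical by construction

    def test_age_slope_ci_covers_zero_under_independence(self):
        """With metric ⟂ age, the OLS slope CI covers 0 in ≥90% of seeded
        replicates (nominal 95%)."""
        cover = 0
        for rep in range(100):
            r = np.random.default_rng(rep)
            age = pd.Series(r.uniform(19, 56, 200))
            metric = pd.Series(r.normal(5, 2, 200))
            sex = pd.Series(r.choice(["F", "M"], 200))
            out = covariate_checks(metric, age, sex)
            ols = next(x for x in out if x.test_name == "ols_slope")
            cover += ols.p_raw >= 0.05
        assert cover >= 90


class TestDupontPower:
    def test_null_size_at_most_level(self):
        size = dupont_paired_power(20, 0.2, 0.2)
        assert 0.0 < size <= 0.05  # exact test is conservative

    def test_monotone_in_n(self):
        powers = [dupont_paired_power(n, 0.45, 0.10) for n in (10, 20, 40, 80)]
        assert all(b >= a - 1e-12 for a, b in zip(powers, powers[1:]))

    def test_pilot_power_matches_monte_carlo(self, rng):
        """Exact enumeration vs 100k simulated pilot cohorts (20 pairs,
        discordance 45% / 10%)."""
        n, p10, p01 = 20, 0.45, 0.10
        exact = dupont_paired_power(n, p10, p01)
        reps = 100_000
        m = rng.binomial(n, p10 + p01, size=reps)
        b = rng.binomial(m, p10 / (p10 + p01))
        ptab = {(bb, mm): mcnemar_exact(bb, mm - bb)
                for mm in range(n + 1) for bb in range(mm + 1)}
        rejected = np.array([ptab[(bb, mm)] <= 0.05 for bb, mm in zip(b, m)])
        assert exact == pytest.approx(rejected.mean(), abs=0.01)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(StatsError):
            dupont_paired_power(20, 0.7, 0.6)
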