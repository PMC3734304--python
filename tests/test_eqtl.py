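import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cistrend import (
    CisWindow,
    CountMatrix,
    GenotypeMatrix,
    PermutationPlan,
    UntestableVariant,
    VariantMeta,
    directional_test,
    group_by_genotype,
    jt_statistic,
    linear_eqtl,
    normalize,
    pairwise_probabilistic_indices,
    run_scan,
    select_cis_variants,
    size_factors,
)

V = VariantMeta("v", "13", 1, "A", "G")

# Positions of the five linear-model eSNPs in the 13q14 window
ESNP_POSITIONS = [49_321_044, 50_033_188, 50_443_527, 50_782_599, 50_945_011]


def _gm(positions, chroms=None):
    chroms = chroms or ["13"] * len(positions)
    variants = [
        VariantMeta(f"v{i}", c, p, "A", "G")
        for i, (c, p) in enumerate(zip(chroms, positions))
    ]
    dosage = np.zeros((3, len(positions)))
    return GenotypeMatrix(["a", "b", "c"], variants, dosage)


class TestCisWindow:
    def test_narrowing_to_200kb_keeps_only_setdb2_snp(self):
        """With the anchor at 50.2 Mb, shrinking the window from 1 Mb to
        200 kb leaves exactly one of the five linear-model eSNP positions."""
        g = _gm(ESNP_POSITIONS)
        w1mb = CisWindow("13", 50_200_000, 1_000_000)
        assert select_cis_variants(g, w1mb).n_variants == 5
        w200k = CisWindow("13", 50_200_000, 200_000)
        kept = select_cis_variants(g, w200k)
        assert [v.pos for v in kept.variants] == [50_033_188]

    def test_boundaries_inclusive_both_ends(self):
        g = _gm([999_999, 1_000_000, 3_000_000, 3_000_001])
        kept = select_cis_variants(g, CisWindow("13", 2_000_000, 1_000_000))
        assert [v.pos for v in kept.variants] == [1_000_000, 3_000_000]

    def test_other_chromosome_excluded(self):
        g = _gm([100, 100], chroms=["13", "7"])
        kept = select_cis_variants(g, CisWindow("13", 100, 1_000_000))
        assert [v.chrom for v in kept.variants] == ["13"]

    def test_zero_survivors_errors_with_window_echo(self):
        g = _gm([100])
        with pytest.raises(ValueError, match="13:5000000"):
            select_cis_variants(g, CisWindow("13", 5_000_000, 10))


class TestGroupByGenotype:
    def test_basic_split(self):
        g = group_by_genotype([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6])
        assert g.levels == [0, 1, 2]
        assert [list(v) for v in g.values] == [[1, 2], [3, 4], [5, 6]]

    def test_monomorphic_untestable(self):
        with pytest.raises(UntestableVariant):
            group_by_genotype([0, 0, 0, 0], [1, 2, 3, 4])

    def test_missing_dosage_dropped_everywhere(self):
        g = group_by_genotype(
            [0, np.nan, 0, 1, 1], [10.0, 99.0, 11.0, 20.0, 21.0]
        )
        assert g.n == 4
        assert 99.0 not in np.concatenate(g.values)

    def test_min_group_n_enforced(self):
        # one group of 5 and one singleton: only 1 usable group at n >= 2
        with pytest.raises(UntestableVariant):
            group_by_genotype([0] * 5 + [1], list(range(6)), min_group_n=2)


class TestLinearEqtl:
    def test_hand_worked_ols(self):
        rec = linear_eqtl(V, np.array([0, 0, 1, 1, 2, 2]),
                          np.array([1, 2, 2, 3, 3, 4]))
        assert rec.group_summary["slope"] == pytest.approx(1.0)
        assert rec.group_summary["se"] == pytest.approx(0.30618621, abs=1e-6)
        assert rec.statistic == pytest.approx(3.26598632, abs=1e-6)
        assert rec.group_summary["df"] == 4
        assert rec.p == pytest.approx(0.0309058, abs=1e-5)
        assert rec.direction == "increasing"

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        x = rng.integers(0, 3, size=40).astype(float)
        y = 0.4 * x + rng.normal(size=40)
        rec = linear_eqtl(V, x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert rec.statistic == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert rec.p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_null_p_uniform(self, rng):
        """Under the null with Gaussian errors the t-test p is exactly
        uniform; check with a KS test over 800 simulated datasets."""
        ps = []
        for _ in range(800):
            x = rng.binomial(2, 0.4, size=40).astype(float)
            if len(np.unique(x)) < 2:
                continue
            ps.append(linear_eqtl(V, x, rng.normal(size=40)).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_perfect_fit_sets_degeneracy_flag(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        rec = linear_eqtl(V, x, x.copy())
        assert rec.degenerate and rec.p == 0.0
        assert rec.group_summary["slope"] == pytest.approx(1.0)

    def test_constant_dosage_untestable(self):
        with pytest.raises(UntestableVariant):
            linear_eqtl(V, np.ones(6), np.arange(6.0))

    def test_missing_dosages_complete_case(self):
        x = np.array([0, 0, 1, 1, 2, 2, np.nan])
        y = np.array([1, 2, 2, 3, 3, 4, 1e9])
        rec = linear_eqtl(V, x, y)
        assert rec.group_summary["n"] == 6
        assert rec.group_summary["slope"] == pytest.approx(1.0)


class TestJtStatistic:
    def test_fully_ordered_groups_attain_maximum(self):
        g = group_by_genotype([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6])
        assert jt_statistic(g) == 12.0  # 3 pairs x 4 cross-pairs each
        pi = pairwise_probabilistic_indices(g)
        assert pi == {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0}

    def test_all_ties_give_half_the_cross_pairs(self):
        g = group_by_genotype([0, 0, 1, 1, 2, 2], [5.0] * 6)
        assert jt_statistic(g) == g.total_cross_pairs / 2 == 6.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_reversing_group_order_is_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        dos = rng.integers(0, 3, size=n).astype(float)
        if len(set(dos)) < 2:
            dos[: n // 2] = 0
            dos[n // 2:] = 1
        expr = rng.normal(size=n).round(1)  # rounding forces some ties
        g_fwd = group_by_genotype(dos, expr, min_group_n=1)
        g_rev = group_by_genotype(2 - dos, expr, min_group_n=1)
        assert jt_statistic(g_fwd) + jt_statistic(g_rev) == pytest.approx(
            g_fwd.total_cross_pairs
        )


class TestDirectionalTest:
    def test_enumeration_worked_example(self):
        """{1,2},{3,4},{5,6}: 90 distinct assignments, only the observed one
        attains T = 12, so exact one-sided p = 1/90 and reported p = 2/90."""
        g = group_by_genotype([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6])
        rec = directional_test(V, g, PermutationPlan(seed=0))
        assert rec.group_summary["mode"] == "enumeration"
        assert rec.group_summary["p_inc"] == pytest.approx(1 / 90)
        assert rec.p == pytest.approx(2 / 90)
        assert rec.direction == "increasing"

    def test_identical_group_multisets_give_p_one(self):
        g = group_by_genotype([0, 0, 1, 1], [3.0, 7.0, 3.0, 7.0])
        rec = directional_test(V, g, PermutationPlan(seed=0))
        assert rec.p == 1.0
        assert rec.direction == "none"

    def test_negating_expression_flips_direction(self):
        expr = np.array([1.0, 3.0, 2.0, 6.0, 5.0, 9.0])
        dos = [0, 0, 1, 1, 2, 2]
        plan = PermutationPlan(seed=5)
        a = directional_test(V, group_by_genotype(dos, expr), plan)
        b = directional_test(V, group_by_genotype(dos, -expr), plan)
        assert a.group_summary["p_inc"] == pytest.approx(b.group_summary["p_dec"])
        assert a.group_summary["p_dec"] == pytest.approx(b.group_summary["p_inc"])
        assert {a.direction, b.direction} == {"increasing", "decreasing"}

    def test_rank_invariance_under_monotone_transform(self, rng):
        dos = rng.binomial(2, 0.4, size=30).astype(float)
        expr = rng.normal(size=30)
        plan = PermutationPlan(B=500, seed=11, enumeration_cap=10)
        a = directional_test(V, group_by_genotype(dos, expr), plan)
        b = directional_test(V, group_by_genotype(dos, np.exp(expr)), plan)
        c = directional_test(
            V, group_by_genotype(dos, stats.rankdata(expr)), plan
        )
        assert a.statistic == b.statistic == c.statistic
        assert a.p == b.p == c.p

    def test_monte_carlo_close_to_enumeration(self, rng):
        dos = np.repeat([0, 1, 2], 3).astype(float)
        expr = rng.normal(size=9)
        g = group_by_genotype(dos, expr)
        exact = directional_test(V, g, PermutationPlan(seed=1))
        assert exact.group_summary["mode"] == "enumeration"
        mc = directional_test(
            V, g, PermutationPlan(B=20_000, seed=1, enumeration_cap=10)
        )
        for side in ("p_inc", "p_dec"):
            p = exact.group_summary[side]
            se = np.sqrt(p * (1 - p) / 20_000)
            assert abs(mc.group_summary[side] - p) <= 3 * se + 1e-4

    def test_small_B_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            PermutationPlan(B=50)

    def test_deterministic_given_seed(self, rng):
        dos = rng.binomial(2, 0.3, size=40).astype(float)
        expr = rng.normal(size=40)
        g = group_by_genotype(dos, expr)
        plan = PermutationPlan(B=300, seed=42, enumeration_cap=10)
        a = directional_test(V, g, plan)
        b = directional_test(V, g, plan)
        assert a.p == b.p and a.statistic == b.statistic


class TestRunScan:
    def _dataset(self, rng, n=40, n_var=6, positions=None):
        positions = positions or [1000 * (i + 1) for i in range(n_var)]
        variants = [
            VariantMeta(f"v{i}", "13", p, "A", "G")
            for i, p in enumerate(positions)
        ]
        dosage = rng.binomial(2, 0.4, size=(n, n_var)).astype(float)
        samples = [f"s{i}" for i in range(n)]
        g = GenotypeMatrix(samples, variants, dosage)
        counts = rng.integers(10, 1000, size=(5, n))
        cm = CountMatrix([f"g{i}" for i in range(5)], samples, counts)
        expr = normalize(cm, size_factors(cm))
        return g, expr

    def test_window_zero_keeps_anchor_variant_only(self, rng):
        g, expr = self._dataset(rng)
        res = run_scan(g, expr, "g0", CisWindow("13", 3000, 0),
                       PermutationPlan(B=200, seed=1))
        assert len(res.linear) == len(res.directional) == 1
        assert res.linear[0].variant.id == "v2"

    def test_monomorphic_variants_skipped_not_fatal(self, rng):
        g, expr = self._dataset(rng)
        g.dosage[:, 0] = 0.0  # monomorphic
        res = run_scan(g, expr, "g0", CisWindow("13", 3000, 10_000),
                       PermutationPlan(B=200, seed=1))
        assert res.n_skipped == 1
        assert res.skipped[0][0] == "v0"
        assert len(res.linear) == 5

    def test_missing_gene_and_empty_intersection_fatal(self, rng):
        g, expr = self._dataset(rng)
        plan = PermutationPlan(B=200, seed=1)
        w = CisWindow("13", 3000, 10_000)
        with pytest.raises(ValueError, match="not in expression"):
            run_scan(g, expr, "nope", w, plan)
        g2 = GenotypeMatrix(["zz"], g.variants, np.zeros((1, 6)))
        with pytest.raises(ValueError, match="no samples shared"):
            run_scan(g2, expr, "g0", w, plan)

    def test_sample_subset_restricts_scan(self, rng):
        g, expr = self._dataset(rng, n=40)
        res = run_scan(g, expr, "g0", CisWindow("13", 3000, 10_000),
                       PermutationPlan(B=200, seed=1),
                       sample_subset=[f"s{i}" for i in range(20)])
        assert res.linear[0].group_summary["n"] == 20

    def test_results_independent_of_variant_order(self, rng):
        """Child seeds derive from variant ids, so reversing the variant
        order must not change any per-variant p-value."""
        g, expr = self._dataset(rng)
        plan = PermutationPlan(B=300, seed=9, enumeration_cap=10)
        w = CisWindow("13", 3000, 10_000)
        res = run_scan(g, expr, "g0", w, plan)
        g_rev = GenotypeMatrix(
            list(g.samples), g.variants[::-1], g.dosage[:, ::-1]
        )
        res_rev = run_scan(g_rev, expr, "g0", w, plan)
        fwd = {r.variant.id: r.p for r in res.directional}
        rev = {r.variant.id: r.p for r in res_rev.directional}
        assert fwd == rev
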