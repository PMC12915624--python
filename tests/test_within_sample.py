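"""Allele-resolved tests: Fisher exact, fold change, chi-square / Cramer's V.

The Fisher implementation is checked against an independent brute-force
oracle that enumerates every table with the observed margins and sums the
probabilities of tables at most as likely as the observed one, computed
with exact rational arithmetic from factorials.
"""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirmut.synthetic_data import SimulationConfig, simulate_cohort, EffectSpec
from mirmut.pipeline import class_count_vector
from mirmut.within_sample_stats import (
    adjust_pvalues,
    call_exp1,
    call_exp2,
    chi2_stat,
    cramers_v_from_counts,
    exp1_test,
    exp2_test,
    fisher_exact_2x2,
    pairwise_profile_v,
    v_strength,
)


def oracle_fisher(a, b, c, d):
    """Exhaustive hypergeometric enumeration with Fraction/factorial arithmetic."""
    f = math.factorial
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return Fraction(1)

    def prob(x):
        y = c1 - x
        if y < 0 or y > r2:
            return Fraction(0)
        return Fraction(f(r1) * f(r2) * f(c1) * f(n - c1), f(n) * f(x) * f(r1 - x) * f(y) * f(r2 - y))

    p_obs = prob(a)
    total = sum((px for x in range(0, min(r1, c1) + 1) if (px := prob(x)) <= p_obs), Fraction(0))
    return min(total, Fraction(1))


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_2x2(50, 50, 50, 50) == 1.0

    @pytest.mark.parametrize("table", [(0, 0, 3, 5), (2, 4, 0, 0), (0, 5, 0, 7), (3, 0, 2, 0)])
    def test_degenerate_margins_give_one(self, table):
        assert fisher_exact_2x2(*table) == 1.0

    @pytest.mark.parametrize("table", [(2, 98, 50, 50), (20, 68, 67, 548), (5, 1, 2, 9)])
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact_2x2(*table) == pytest.approx(float(oracle_fisher(*table)), rel=1e-12)

    def test_printed_homozygosity_table(self):
        # frozen from the enumeration oracle for the 20/88 vs 67/615 counts
        p = fisher_exact_2x2(20, 68, 67, 548)
        assert p == pytest.approx(0.003064891345942792, rel=1e-12)
        odds = (20 * 548) / (68 * 67)
        assert round(odds, 3) == pytest.approx(2.406, abs=1e-9)
        assert odds == pytest.approx(2.405, abs=1e-3)

    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=300, deadline=None)
    def test_oracle_equivalence_property(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            float(oracle_fisher(a, b, c, d)), rel=1e-12)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-6)


class TestExp1:
    def test_equal_fractions(self):
        r = exp1_test(50, 50, 30, 30)
        assert r.log2fc == 0.0 and r.p == 1.0

    def test_total_loss_of_mutant_reads(self):
        r = exp1_test(0, 100, 40, 60)
        assert r.log2fc < 0
        assert r.p == pytest.approx(float(oracle_fisher(0, 100, 40, 60)), rel=1e-12)

    def test_symmetry_swapping_rna_and_dna(self):
        a = exp1_test(30, 70, 55, 45)
        b = exp1_test(55, 45, 30, 70)
        assert a.p == b.p
        assert a.log2fc == pytest.approx(-b.log2fc)

    def test_calls_require_adjusted_p_and_fold_change(self):
        results = [
            exp1_test(5, 495, 50, 50),    # strong decrease
            exp1_test(48, 52, 50, 50),    # null
            exp1_test(90, 10, 40, 60),    # strong increase
        ]
        called = call_exp1(results, alpha=0.05, min_abs_log2fc=1.0)
        assert [r.call for r in called] == ["decrease", "ns", "increase"]
        for r in called:
            if r.call != "ns":
                assert r.p_adj < 0.05 and abs(r.log2fc) >= 1.0
                assert (r.log2fc > 0) == (r.call == "increase")


class TestAdjustment:
    def test_single_p_unchanged_under_bh(self):
        assert adjust_pvalues([0.037])[0] == pytest.approx(0.037)

    def test_bh_step_up_hand_computed(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_bonferroni(self):
        ps = [0.004] + [0.5] * 9
        assert adjust_pvalues(ps, "bonferroni")[0] == pytest.approx(0.04)

    def test_empty(self):
        assert adjust_pvalues([]).size == 0


def oracle_chi2(table):
    """Sum over cells of (O-E)^2/E with E from the margin products."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    return float(((table - expected) ** 2 / expected).sum())


class TestChiSquareAndCramersV:
    def test_proportional_rows_give_zero(self):
        wt = np.array([30, 9, 6, 3, 3, 3, 2, 2, 2])
        r = exp2_test(wt, 3 * wt, pseudocount=0)
        assert r.chi2 == pytest.approx(0.0, abs=1e-10)
        assert r.cramers_v == pytest.approx(0.0, abs=1e-6)

    @given(st.integers(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_chi2_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 60, size=(2, 3)).astype(float)
        assert chi2_stat(table) == pytest.approx(oracle_chi2(table), rel=1e-10)
        assert cramers_v_from_counts(table) == pytest.approx(
            math.sqrt(oracle_chi2(table) / table.sum()), rel=1e-10)

    def test_strength_bins(self):
        assert v_strength(0.05) == "none"
        assert v_strength(0.15) == "small"
        assert v_strength(0.3) == "medium"
        assert v_strength(0.638) == "large"  # the strongest printed association bin

    @given(st.integers(0, 20))
    @settings(max_examples=60, deadline=None)
    def test_v_bounded_and_row_swap_invariant(self, seed):
        rng = np.random.default_rng(1000 + seed)
        wt = rng.integers(0, 200, size=9)
        mut = rng.integers(0, 200, size=9)
        r = exp2_test(wt, mut)
        r_swapped = exp2_test(mut, wt)
        assert 0.0 <= r.cramers_v <= 1.0
        assert r.cramers_v == pytest.approx(r_swapped.cramers_v, rel=1e-12)
        assert r.chi2 == pytest.approx(r_swapped.chi2, rel=1e-12)

    def test_call_rule(self):
        wt = np.array([500, 50, 50, 20, 20, 20, 10, 10, 10])
        shifted = np.array([50, 500, 50, 20, 20, 20, 10, 10, 10])
        called = call_exp2([exp2_test(wt, shifted), exp2_test(wt, wt)])
        assert called[0].call and called[0].cramers_v > 0.2 and called[0].p_adj < 1e-11
        assert not called[1].call


def _allele_class_counts(cohort, sample_id, allele):
    recs = cohort.isomirs
    sel = recs[(recs["sample_id"] == sample_id) & (recs["arm"] == "5p")
               & (recs["allele"] == allele)]
    return class_count_vector(sel, scheme="nine")


class TestPairwiseV:
    def test_identical_vectors_give_zero(self):
        v = pairwise_profile_v([[30, 10, 5], [30, 10, 5]])
        assert v.shape == (1,) and v[0] == pytest.approx(0.0, abs=1e-9)

    def test_singleton_group_empty(self):
        assert pairwise_profile_v([[30, 10, 5]]).size == 0

    def test_null_cohort_pairwise_v_below_threshold(self):
        """Same-template samples vary far less than the V > 0.2 call bound."""
        cfg = SimulationConfig(n_wt_samples=12)
        cohort = simulate_cohort(cfg, effects=(), seed=7)
        vecs = [_allele_class_counts(cohort, s, "WT")
                for s in cohort.isomirs["sample_id"].unique()]
        vs = pairwise_profile_v([v for v in vecs if v.sum() >= 50])
        assert np.median(vs) < 0.2

    def test_injected_shift_separates_mut_from_wt_pairs(self):
        """WT-vs-MUT V exceeds WT-vs-WT V when a class shift is injected."""
        shift = (("0|0", "0|+", 0.3),)
        effects = [EffectSpec(mutation_id=f"M{i}", vaf_dna=0.5, class_shift=shift)
                   for i in range(4)]
        cohort = simulate_cohort(SimulationConfig(n_wt_samples=4), effects, seed=11)
        mut_samples = cohort.mutations["sample_id"].tolist()
        wt_vecs = [_allele_class_counts(cohort, s, "WT") for s in mut_samples]
        mut_vecs = [_allele_class_counts(cohort, s, "MUT") for s in mut_samples]
        v_within = pairwise_profile_v(wt_vecs)
        v_cross = np.array([cramers_v_from_counts(np.vstack([w, m]) + 5)
                            for w, m in zip(wt_vecs, mut_vecs)])
        assert np.median(v_cross) > np.median(v_within)
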