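import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coinv import (
    GenotypeCounts,
    allele_balance_chi2,
    sd_table,
    selection_mode_test,
    williams_g_test,
)
from coinv.segdist import williams_q

LN10 = np.log(10.0)

counts_strategy = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda c: sum(c) >= 1)


class TestWilliamsG:
    def test_exact_mendelian_counts_give_zero(self):
        r = williams_g_test(GenotypeCounts(25, 50, 25))
        assert r.G == pytest.approx(0.0, abs=1e-12)
        assert r.p == 1.0
        assert r.SDV == pytest.approx(0.0, abs=1e-12)

    def test_zero_count_error_paths(self):
        with pytest.raises(ValueError):
            GenotypeCounts(0, 0, 0)
        with pytest.raises(ValueError):
            GenotypeCounts(-1, 2, 3)

    @given(counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_sdv_matches_g_for_two_df(self, c):
        # for df 2 the chi-square tail is exp(-G/2), so SDV·2·ln10 = G
        r = williams_g_test(GenotypeCounts(*c))
        assert r.SDV * 2 * LN10 == pytest.approx(r.G, rel=1e-9)

    @given(counts_strategy)
    @settings(max_examples=60, deadline=None)
    def test_invariant_under_joint_category_permutation(self, c):
        base = williams_g_test(GenotypeCounts(*c)).G
        perm = GenotypeCounts(c[2], c[0], c[1])
        g_perm = williams_g_test(perm, expected=(0.25, 0.25, 0.5)).G
        assert g_perm == pytest.approx(base, rel=1e-12, abs=1e-12)

    def test_correction_vanishes_for_large_samples(self):
        assert williams_q(100_000, 3) == pytest.approx(1.0, abs=1e-4)
        # corrected and raw G differ by < 1% beyond N = 68
        assert williams_q(68, 3) - 1.0 < 0.01


class TestAlleleBalance:
    @given(counts_strategy)
    @settings(max_examples=100, deadline=None)
    def test_zero_iff_homozygote_classes_balanced(self, c):
        stat, p = allele_balance_chi2(GenotypeCounts(*c))
        if c[0] == c[2]:
            assert stat == pytest.approx(0.0, abs=1e-12)
        else:
            assert stat > 0


class TestSelectionMode:
    def test_mendelian_counts_classified_none(self):
        for variant in ("one_two_one", "hwe_conditional"):
            r = selection_mode_test(GenotypeCounts(25, 50, 25), variant=variant)
            assert r.chi2 == pytest.approx(0.0, abs=1e-12)
            assert r.mode == "none"

    def test_hwe_conditional_matches_direct_formula(self):
        # independent hand computation of the HWE-conditional chi-square
        n_rr, n_ri, n_ii = 53, 95, 3
        N = n_rr + n_ri + n_ii
        p = (2 * n_rr + n_ri) / (2 * N)
        q = 1 - p
        e = [N * p * p, 2 * N * p * q, N * q * q]
        expect = sum((o - ee) ** 2 / ee for o, ee in zip((n_rr, n_ri, n_ii), e))
        r = selection_mode_test(GenotypeCounts(n_rr, n_ri, n_ii), variant="hwe_conditional")
        assert r.chi2 == pytest.approx(expect, rel=1e-12)
        assert r.df2 == 1

    def test_degenerate_allele_frequency_flagged(self):
        r = selection_mode_test(GenotypeCounts(10, 0, 0), variant="hwe_conditional")
        assert r.degenerate
        assert np.isnan(r.chi2)

    def test_pure_zygotic_pattern(self):
        # balanced alleles but badly distorted genotype distribution
        r = selection_mode_test(GenotypeCounts(50, 10, 50))
        assert r.p1 > 0.05
        assert r.mode == "zygotic"


class TestSdTable:
    def test_single_locus_adjustment_is_identity(self, toy_matrix):
        sub = toy_matrix.data[["Inv_A"]]
        from coinv import GenotypeMatrix

        df = sd_table(GenotypeMatrix(sub, cross_id="t"))
        assert len(df) == 1
        assert df.loc[0, "p_adj"] == pytest.approx(df.loc[0, "p"])

    def test_recessive_lethal_locus_ranks_first(self):
        from coinv import CrossConfig, simulate_f2_cross

        loci = [(f"L{i}", f"chr{i % 5 + 1}", True) for i in range(8)]
        cfg = CrossConfig(
            cross_id="x", n_individuals=300, loci=loci,
            single_locus_survival={"L3": (1.0, 1.0, 0.0)}, seed=3,
        )
        m, _ = simulate_f2_cross(cfg)
        df = sd_table(m)
        assert df.loc[0, "locus"] == "L3"
        assert df.loc[0, "n_II"] == 0
        assert df.loc[0, "mode"] == "zygotic"

    def test_null_cross_rejection_rate_near_alpha(self):
        from coinv import CrossConfig, simulate_f2_cross

        loci = [(f"L{i}", f"chr{i % 10 + 1}", True) for i in range(64)]
        cfg = CrossConfig(cross_id="null", n_individuals=150, loci=loci, seed=29)
        m, _ = simulate_f2_cross(cfg)
        df = sd_table(m)
        k = int((df["p"] < 0.05).sum())
        lo, hi = stats.binom.interval(0.99, 64, 0.05)
        assert lo <= k <= hi
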