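import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from coinv import (
    GenotypeMatrix,
    Table2x2,
    affinity_alpha,
    centered_jaccard,
    jaccard_bootstrap_test,
    pairwise_contrasts,
)
from coinv.cooccurrence import centered_jaccard_table, jaccard_bootstrap_from_table

from _oracles import exact_permutation_jaccard_p, grid_affinity_mle

nondegenerate_tables = st.tuples(*[st.integers(0, 40)] * 4).filter(
    lambda c: (c[0] + c[1]) > 0 and (c[0] + c[2]) > 0
    and (c[2] + c[3]) > 0 and (c[1] + c[3]) > 0
)


class TestCenteredJaccard:
    def test_balanced_independent_table_is_zero(self):
        assert centered_jaccard_table(Table2x2(25, 25, 25, 25)) == pytest.approx(0.0)

    def test_identical_vectors_at_half_prevalence(self):
        x = [1, 0] * 50
        assert centered_jaccard(x, x) == pytest.approx(1.0 - 1.0 / 3.0)

    def test_complementary_vectors_are_negative(self):
        x = [1] * 4 + [0] * 4
        y = [0] * 4 + [1] * 4
        cjt = centered_jaccard(x, y)
        assert cjt == pytest.approx(-0.25 / 0.75)  # -E[J] at p = q = 1/2

    def test_all_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            centered_jaccard([0, 0, 0, 1], [0, 0, 0, 0])

    @given(nondegenerate_tables)
    @settings(max_examples=80, deadline=None)
    def test_symmetric_in_the_two_vectors(self, cells):
        t = Table2x2(*cells)
        swapped = Table2x2(t.n11, t.n01, t.n10, t.n00)
        assert centered_jaccard_table(t) == pytest.approx(
            centered_jaccard_table(swapped), abs=1e-12
        )

    def test_invariant_to_simultaneous_permutation(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 60)
        y = rng.integers(0, 2, 60)
        if x.sum() == 0 or y.sum() == 0:
            x[0] = y[0] = 1
        perm = rng.permutation(60)
        assert centered_jaccard(x, y) == pytest.approx(centered_jaccard(x[perm], y[perm]))


class TestJaccardBootstrap:
    def test_tiny_n_matches_exhaustive_permutation(self):
        x = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        y = np.array([1, 1, 0, 0, 1, 0, 0, 0])
        exact = exact_permutation_jaccard_p(x, y)
        B = 20_000
        p = jaccard_bootstrap_test(x, y, B=B, seed=5)
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(p - exact) <= 3 * se + 2 / (B + 1)

    def test_identical_vectors_give_floor_p(self):
        x = np.array([1, 0] * 50)
        p = jaccard_bootstrap_test(x, x, B=2000, seed=1)
        assert p < 0.01

    def test_calibration_under_independence(self):
        rng = np.random.default_rng(21)
        n_reps, B = 300, 199
        rej = 0
        for _ in range(n_reps):
            x = rng.integers(0, 2, 200)
            y = rng.integers(0, 2, 200)
            if 0 < x.sum() < 200 and 0 < y.sum() < 200:
                rej += jaccard_bootstrap_test(x, y, B=B, rng=rng) <= 0.05
        from scipy import stats

        lo, hi = stats.binom.interval(0.999, n_reps, 0.05)
        assert lo <= rej <= hi

    def test_missing_entries_dropped_pairwise(self):
        x = np.array([1, 0, 1, 0, np.nan, 1])
        y = np.array([1, 0, 0, 1, 1, np.nan])
        t = Table2x2.from_vectors(x, y)
        assert t.n == 4  # only pairwise-complete individuals counted


class TestAffinity:
    def test_balanced_table_gives_zero(self):
        assert affinity_alpha(Table2x2(25, 25, 25, 25)).alpha == pytest.approx(0.0, abs=1e-6)

    def test_boundary_tables_capped(self):
        assert affinity_alpha(Table2x2(10, 0, 0, 10)).alpha == 10.0
        assert affinity_alpha(Table2x2(0, 10, 10, 0)).alpha == -10.0

    def test_mle_matches_dense_grid_search(self):
        t = Table2x2(8, 2, 3, 7)
        expect = grid_affinity_mle(t.n11, t.n, t.mA, t.mB)
        got = affinity_alpha(t).alpha
        assert got == pytest.approx(expect, abs=1e-3)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            affinity_alpha(Table2x2(5, 5, 0, 0))

    @given(st.tuples(*[st.integers(1, 25)] * 4))
    @settings(max_examples=40, deadline=None)
    def test_log_odds_antisymmetry_under_column_swap(self, cells):
        t = Table2x2(*cells)
        a1 = affinity_alpha(t)
        a2 = affinity_alpha(Table2x2(t.n10, t.n11, t.n00, t.n01))
        assume(not a1.capped and not a2.capped)
        assert a1.alpha == pytest.approx(-a2.alpha, abs=1e-4)

    @given(st.tuples(*[st.integers(1, 25)] * 4))
    @settings(max_examples=60, deadline=None)
    def test_sign_agreement_with_cross_product(self, cells):
        t = Table2x2(*cells)
        cross = t.n11 * t.n00 - t.n10 * t.n01
        alpha = affinity_alpha(t).alpha
        cjt = centered_jaccard_table(t)
        if cross > 0:
            assert alpha > 0 and cjt > 0
        elif cross < 0:
            assert alpha < 0


class TestPairwiseContrasts:
    def test_planted_repulsion_detected_in_submatrix_two(self, repulsion_cross):
        pr = pairwise_contrasts(repulsion_cross, "Inv_1", "Inv_2", B=2000, seed=2)
        sub2 = {c.submatrix: c for c in pr.contrasts}[2]
        assert sub2.cJT < 0
        assert sub2.alpha < 0
        assert sub2.SR < 0

    def test_contrasts_with_constant_state_are_skipped(self):
        df = pd.DataFrame(
            {
                "A": ["RR", "RI", "RI", "RR", "RI", "II"],
                "B": ["RR", "RI", "RR", "RI", "RI", "RR"],  # no II carriers
            },
            index=[f"i{k}" for k in range(6)],
            dtype=object,
        )
        pr = pairwise_contrasts(GenotypeMatrix(df), "A", "B", B=50, seed=0)
        skipped = {s for s, _ in pr.skipped}
        assert skipped == {2, 3}  # every contrast needing B's HOM_INV state

    def test_same_chromosome_pair_rejected(self, toy_matrix):
        meta = pd.Series({"Inv_A": "chr1", "Inv_B": "chr1", "Inv_C": "chr2"})
        with pytest.raises(ValueError, match="same chromosome"):
            pairwise_contrasts(toy_matrix, "Inv_A", "Inv_B", meta=meta, B=10)

    def test_mendelian_pair_mostly_non_significant(self, mendelian_cross):
        pr = pairwise_contrasts(mendelian_cross, "Inv_1", "Inv_2", B=500, seed=8)
        assert not any(c.detected_by_all for c in pr.contrasts)
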