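"""Haplotype frequency estimation and Hedrick's D'."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntrtest.containers import RegionGenotypes
from ntrtest.ld import (
    HaplotypeFreqTable,
    haplotype_freqs_em,
    haplotype_freqs_phased,
    hedrick_dprime,
    pairwise_dprime_matrix,
)


def _table(h_ab, h_aB, h_Ab, h_AB):
    """Build a table with row 1 = allele A, col 1 = allele B."""
    return HaplotypeFreqTable(h=np.array([[h_ab, h_aB], [h_Ab, h_AB]]))


def classical_abs_dprime(h):
    """Independent oracle: Lewontin |D'| = |D| / Dmax from the 2x2 table."""
    pA = h[1, 0] + h[1, 1]
    qB = h[0, 1] + h[1, 1]
    D = h[1, 1] - pA * qB
    if D == 0:
        return 0.0
    if D > 0:
        dmax = min(pA * (1 - qB), (1 - pA) * qB)
    else:
        dmax = min(pA * qB, (1 - pA) * (1 - qB))
    return abs(D / dmax)


class TestPhasedCounting:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            # 4x AB + 4x ab -> h = diag(0.5, 0.5)
            ([1] * 4 + [0] * 4, [1] * 4 + [0] * 4,
             [[0.5, 0.0], [0.0, 0.5]]),
            # all four haplotypes twice -> uniform table
            ([1, 1, 0, 0] * 2, [1, 0, 1, 0] * 2,
             [[0.25, 0.25], [0.25, 0.25]]),
            # 5 AB, 2 Ab, 1 aB, 2 ab out of 10
            ([1] * 7 + [0] * 3, [1] * 5 + [0, 0] + [1] + [0, 0],
             [[0.2, 0.1], [0.2, 0.5]]),
        ],
    )
    def test_direct_counts(self, a, b, expected):
        t = haplotype_freqs_phased(np.array(a), np.array(b))
        np.testing.assert_allclose(t.h, expected)

    def test_zero_haplotypes_errors(self):
        with pytest.raises(ValueError):
            haplotype_freqs_phased(np.array([]), np.array([]))


class TestHedrickDprime:
    def test_independence_is_zero(self):
        t = _table(0.5 * 0.6, 0.5 * 0.4, 0.5 * 0.6, 0.5 * 0.4)
        assert hedrick_dprime(t) == 0.0

    def test_complete_ld_is_one(self):
        t = _table(0.7, 0.0, 0.0, 0.3)
        assert hedrick_dprime(t) == pytest.approx(1.0)

    def test_hand_worked_value(self):
        # h_AB=0.5, h_Ab=0.2, h_aB=0.1, h_ab=0.2: p_A=0.7, q_B=0.6,
        # D=0.08, Dmax=min(0.28, 0.18)=0.18 -> D'=4/9
        t = _table(0.2, 0.1, 0.2, 0.5)
        assert hedrick_dprime(t) == pytest.approx(4.0 / 9.0, abs=1e-12)

    def test_degenerate_table_errors(self):
        t = HaplotypeFreqTable(h=np.array([[0.4, 0.6], [0.0, 0.0]]),
                               degenerate=True)
        with pytest.raises(ValueError):
            hedrick_dprime(t)

    def test_matches_classical_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            h = rng.dirichlet(np.ones(4)).reshape(2, 2)
            t = HaplotypeFreqTable(h=h)
            if t.degenerate or (t.p == 0).any() or (t.q == 0).any():
                continue
            assert hedrick_dprime(t) == pytest.approx(
                min(classical_abs_dprime(h), 1.0), abs=1e-10
            )

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_allele_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.dirichlet(np.ones(4)).reshape(2, 2)
        t = HaplotypeFreqTable(h=h)
        if (t.p == 0).any() or (t.q == 0).any():
            return
        base = hedrick_dprime(t)
        assert hedrick_dprime(HaplotypeFreqTable(h=h[::-1])) == pytest.approx(base)
        assert hedrick_dprime(HaplotypeFreqTable(h=h[:, ::-1])) == pytest.approx(base)
        assert hedrick_dprime(HaplotypeFreqTable(h=h[::-1, ::-1])) == \
            pytest.approx(base)


def _em_grid_oracle(gA, gB, steps=20001):
    """Brute-force profile of the multinomial likelihood over h_AB."""
    counts = np.zeros((3, 3))
    np.add.at(counts, (gA, gB), 1.0)
    n = gA.size
    pA = gA.sum() / (2 * n)
    qB = gB.sum() / (2 * n)

    def loglik(hAB):
        hAb = pA - hAB
        haB = qB - hAB
        hab = 1 - pA - qB + hAB
        h = np.array([[hab, haB], [hAb, hAB]])
        if (h < 0).any():
            return -np.inf
        # genotype probabilities under HWE from haplotype frequencies
        ll = 0.0
        for i in range(3):
            for m in range(3):
                c = counts[i, m]
                if c == 0:
                    continue
                prob = 0.0
                for (a1, b1) in itertools.product((0, 1), repeat=2):
                    for (a2, b2) in itertools.product((0, 1), repeat=2):
                        if a1 + a2 == i and b1 + b2 == m:
                            prob += h[a1, b1] * h[a2, b2]
                if prob <= 0:
                    return -np.inf
                ll += c * np.log(prob)
        return ll

    lo = max(0.0, pA + qB - 1.0)
    hi = min(pA, qB)
    grid = np.linspace(lo, hi, steps)
    lls = np.array([loglik(g) for g in grid])
    return grid[np.argmax(lls)]


class TestEM:
    def test_no_double_heterozygote_equals_direct_counting(self):
        gA = np.array([0, 0, 2, 2, 1, 0])
        gB = np.array([0, 0, 2, 2, 0, 1])
        t = haplotype_freqs_em(gA, gB)
        # phase unambiguous: count haplotypes directly
        hapA = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 1, 0, 0])
        hapB = np.array([0, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 1])
        expected = haplotype_freqs_phased(hapA, hapB)
        np.testing.assert_allclose(t.h, expected.h, atol=1e-9)

    def test_matches_grid_search_oracle_with_double_het(self):
        gA = np.array([1, 1, 0, 2, 1, 0])
        gB = np.array([1, 1, 0, 2, 0, 0])
        t = haplotype_freqs_em(gA, gB)
        h_ab_ml = _em_grid_oracle(gA, gB)
        assert t.h[1, 1] == pytest.approx(h_ab_ml, abs=1e-4)

    def test_monomorphic_flagged_degenerate(self):
        t = haplotype_freqs_em(np.zeros(6, dtype=int), np.zeros(6, dtype=int))
        assert t.degenerate

    def test_em_approaches_phased_estimate_with_few_double_hets(self):
        rng = np.random.default_rng(5)
        hapA = (rng.random(4000) < 0.3).astype(int)
        hapB = ((rng.random(4000) < 0.15) ^ hapA & 0).astype(int) | (
            (hapA == 1) & (rng.random(4000) < 0.6)
        ).astype(int)
        gA = hapA[0::2] + hapA[1::2]
        gB = hapB[0::2] + hapB[1::2]
        phased = haplotype_freqs_phased(hapA, hapB)
        em = haplotype_freqs_em(gA, gB)
        np.testing.assert_allclose(em.h, phased.h, atol=0.02)


class TestPairwiseMatrix:
    def test_duplicated_variant_gives_one(self):
        X = np.array([[0, 1, 2, 1, 0, 1], [0, 1, 2, 1, 0, 1]], dtype=np.int8)
        H = np.array([[0, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0],
                      [0, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0]], dtype=np.int8)
        region = RegionGenotypes("dup", ["a", "b"], np.array([1, 2]), X,
                                 phased_haplotypes=H)
        ld = pairwise_dprime_matrix(region)
        assert ld.dprime[0, 1] == pytest.approx(1.0)
        assert ld.dprime[0, 0] == 1.0 and ld.dprime[1, 1] == 1.0

    def test_phased_fast_path_matches_per_pair_tables(self):
        rng = np.random.default_rng(3)
        L, n2 = 6, 400
        H = (rng.random((L, n2)) < rng.uniform(0.1, 0.5, (L, 1))).astype(np.int8)
        X = H[:, 0::2] + H[:, 1::2]
        region = RegionGenotypes("r", [f"v{i}" for i in range(L)],
                                 np.arange(L), X, phased_haplotypes=H)
        ld = pairwise_dprime_matrix(region, use_phased=True)
        for i in range(L):
            for m in range(i + 1, L):
                t = haplotype_freqs_phased(H[i], H[m])
                assert ld.dprime[i, m] == pytest.approx(
                    hedrick_dprime(t), abs=1e-10
                )

    def test_independent_variants_have_low_dprime(self):
        rng = np.random.default_rng(9)
        H = (rng.random((2, 20000)) < 0.3).astype(np.int8)
        X = H[:, 0::2] + H[:, 1::2]
        region = RegionGenotypes("r", ["a", "b"], np.array([1, 2]), X,
                                 phased_haplotypes=H)
        ld = pairwise_dprime_matrix(region)
        assert ld.dprime[0, 1] < 0.1

    def test_single_variant_errors(self, tiny_region):
        with pytest.raises(ValueError):
            pairwise_dprime_matrix(tiny_region.subset_variants(np.array([0])))

    def test_em_path_close_to_phased_path(self):
        rng = np.random.default_rng(17)
        L, n2 = 4, 2000
        base = (rng.random(n2) < 0.4).astype(np.int8)
        H = np.array([np.where(rng.random(n2) < 0.7, base,
                               (rng.random(n2) < 0.4).astype(np.int8))
                      for _ in range(L)])
        X = H[:, 0::2] + H[:, 1::2]
        region_ph = RegionGenotypes("r", list("abcd"), np.arange(4), X,
                                    phased_haplotypes=H)
        region_un = RegionGenotypes("r", list("abcd"), np.arange(4), X)
        d_ph = pairwise_dprime_matrix(region_ph).dprime
        d_un = pairwise_dprime_matrix(region_un).dprime
        np.testing.assert_allclose(d_un, d_ph, atol=0.06)
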