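"""Rank-sum statistic, permutation null, and the NTR region test."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from ntrtest.containers import PhenotypeVector, RegionGenotypes
from ntrtest.ld import pairwise_dprime_matrix
from ntrtest.ntr import (
    _bh_adjusted_min,
    _weighted_midrank_sums,
    adaptive_permutation_null,
    fdr_adjust,
    ntr_region_test,
    permutation_null,
    rank_sum_cases,
    test_from_scores,
)
from ntrtest.scoring import VariantStats, genetic_scores, pair_weights


class TestRankSum:
    def test_top_two_cases(self):
        ph = PhenotypeVector(np.array([1, 1, 0, 0]))
        assert rank_sum_cases(np.array([9.0, 8.0, 1.0, 2.0]), ph) == 7.0

    def test_all_tied_gives_midrank_sum(self):
        ph = PhenotypeVector(np.array([1, 1, 0, 0, 0]))
        assert rank_sum_cases(np.zeros(5), ph) == 2 * (5 + 1) / 2

    def test_three_way_tie_midranks(self):
        # scores (0,0,0,5): tied zeros get rank 2 each, the 5 gets rank 4
        ph = PhenotypeVector(np.array([0, 0, 0, 1]))
        assert rank_sum_cases(np.array([0.0, 0.0, 0.0, 5.0]), ph) == 4.0
        ph2 = PhenotypeVector(np.array([1, 0, 0, 0]))
        assert rank_sum_cases(np.array([0.0, 0.0, 0.0, 5.0]), ph2) == 2.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=50)
        ph = PhenotypeVector((rng.random(50) < 0.4).astype(int))
        base = rank_sum_cases(s, ph)
        assert rank_sum_cases(np.exp(s), ph) == base
        assert rank_sum_cases(3 * s + 7, ph) == base


class TestPermutationNull:
    def test_exhaustive_enumeration_matches_oracle(self):
        """m, s agree exactly with independent enumeration on a tiny fixture."""
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        ph = PhenotypeVector(np.array([1, 1, 0, 0]))
        m, s = permutation_null(scores, ph, exact=True)
        # oracle: all C(4,2)=6 case sets of fixed ranks
        ranks = sps.rankdata(scores)
        sums = [ranks[list(c)].sum() for c in combinations(range(4), 2)]
        assert sums == [3, 4, 5, 5, 6, 7]
        assert m[0] == pytest.approx(np.mean(sums))  # = 5
        assert s[0] == pytest.approx(np.std(sums))

    def test_monte_carlo_converges_to_enumeration(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        ph = PhenotypeVector(np.array([1, 1, 0, 0]))
        m, s = permutation_null(scores, ph, n_perm=40000, seed=0)
        assert m[0] == pytest.approx(5.0, abs=0.02)

    def test_tied_scores_zero_sd(self):
        ph = PhenotypeVector(np.array([1, 0, 1, 0]))
        m, s = permutation_null(np.ones(4), ph, n_perm=50, seed=1)
        assert s[0] == 0.0
        assert m[0] == 2 * (4 + 1) / 2

    def test_wilcoxon_closed_form_limit(self):
        """m, s approach n_c (N+1)/2 and sqrt(n_c n_u (N+1)/12)."""
        rng = np.random.default_rng(3)
        N, nc = 200, 90
        scores = rng.normal(size=N)  # distinct scores
        ph = PhenotypeVector(np.array([1] * nc + [0] * (N - nc)))
        m, s = permutation_null(scores, ph, n_perm=30000, seed=4)
        m_theory = nc * (N + 1) / 2
        s_theory = math.sqrt(nc * (N - nc) * (N + 1) / 12)
        assert m[0] == pytest.approx(m_theory, rel=0.002)
        assert s[0] == pytest.approx(s_theory, rel=0.02)

    def test_permuted_sums_normality_large_n(self):
        """Permutation replicates of R pass a normality check at large N."""
        rng = np.random.default_rng(8)
        N = 500
        scores = np.round(rng.exponential(size=N), 1)  # skewed, some ties
        ph = PhenotypeVector((np.arange(N) < 200).astype(int))
        m, s, sums = permutation_null(scores, ph, n_perm=2000, seed=5,
                                      return_samples=True)
        stat, p = sps.normaltest(sums[:, 0])
        assert p > 1e-3


class TestWeightedMidranks:
    def test_matches_rankdata_with_cross_group_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            U = rng.integers(2, 9)
            sizes = rng.integers(1, 5, U).astype(float)
            vals = rng.integers(0, 4, U).astype(float)  # force value ties
            K = np.array([rng.integers(0, s + 1) for s in sizes], dtype=float)
            got = _weighted_midrank_sums(vals[None, :], sizes, K[None, :])[0]
            expanded = np.repeat(vals, sizes.astype(int))
            ranks = sps.rankdata(expanded)
            starts = np.concatenate([[0], np.cumsum(sizes.astype(int))[:-1]])
            expected = sum(
                ranks[int(st)] * k for st, k in zip(starts, K)
            )
            assert got == pytest.approx(expected)


class TestAdaptiveEngine:
    def test_exact_enumeration_matches_brute_force(self):
        """Full pipeline re-estimation per label set equals the engine."""
        rng = np.random.default_rng(4)
        while True:
            X = rng.integers(0, 3, size=(3, 7)).astype(np.int8)
            mn, tot = X.sum(1), 14
            if all(0 < m < tot and m / tot <= 0.5 for m in mn):
                break
        region = RegionGenotypes("t", ["a", "b", "c"], np.arange(3), X)
        ph = PhenotypeVector(np.array([1, 1, 1, 0, 0, 0, 0]))
        stats = VariantStats.from_region(region, ph)
        ld = pairwise_dprime_matrix(region, use_phased=False)
        pairs = pair_weights(stats, ld)

        sums = []
        for cs in combinations(range(7), 3):
            st = np.zeros(7, dtype=np.int8)
            st[list(cs)] = 1
            ph_b = PhenotypeVector(st)
            vs = VariantStats.from_region(region, ph_b)
            pw = pair_weights(vs, ld)
            sc = genetic_scores(region, vs, pw, pr=1.0)
            sums.append([rank_sum_cases(sc.s[k], ph_b) for k in range(3)])
        sums = np.array(sums)
        m, s = adaptive_permutation_null(region, ph, stats, pairs, exact=True)
        np.testing.assert_allclose(m, sums.mean(0))
        np.testing.assert_allclose(s, sums.std(0, ddof=0))


class TestRegionTest:
    def test_p_invariant_to_pr_and_monotone_transform(self, small_simulated):
        """End-to-end p depends only on score ranks."""
        region, ph = small_simulated.region, small_simulated.phenotype
        stats = VariantStats.from_region(region, ph)
        pairs = pair_weights(stats, pairwise_dprime_matrix(region))
        base = genetic_scores(region, stats, pairs)
        r1 = test_from_scores(base, ph, n_perm=300, seed=42)
        doubled = genetic_scores(region, stats, pairs, pr=2 * base.pr)
        r2 = test_from_scores(doubled, ph, n_perm=300, seed=42)
        assert r1.p == r2.p and np.array_equal(r1.r, r2.r)
        import dataclasses
        cubed = dataclasses.replace(base, s=base.s ** 3)  # strictly increasing
        r3 = test_from_scores(cubed, ph, n_perm=300, seed=42)
        assert r1.p == r3.p

    def test_selected_k_attains_smallest_p(self, small_simulated):
        res = ntr_region_test(small_simulated.region, small_simulated.phenotype,
                              n_perm=300, seed=0)
        assert res.p_k[res.k_star - 1] == res.p_k.min()
        assert res.p_uncorrected == pytest.approx(res.p_k.min())
        # the BH-corrected p never undercuts the selected minimum
        assert res.p >= res.p_uncorrected - 1e-12
        assert 0.0 <= res.p <= 1.0

    def test_zero_z_caps_p_at_one(self):
        ph = PhenotypeVector(np.array([1, 1, 0, 0, 1, 0]))
        res = test_from_scores(np.zeros((3, 6)), ph, n_perm=100, seed=1)
        assert res.p == 1.0 and res.degenerate

    def test_single_polymorphic_variant_rejected(self):
        X = np.array([[0, 1, 0, 1], [0, 0, 0, 0]], dtype=np.int8)
        region = RegionGenotypes("r", ["a", "b"], np.arange(2), X)
        ph = PhenotypeVector(np.array([1, 1, 0, 0]))
        with pytest.raises(ValueError, match="polymorphic"):
            ntr_region_test(region, ph, n_perm=50, seed=0)

    def test_power_increases_with_effect_size(self):
        """Monotone power: stronger ORs give more sub-alpha p-values."""
        from ntrtest.simulate import ScenarioConfig, sample_case_control

        hits = {1.2: 0, 2.5: 0}
        for orx in hits:
            cfg = ScenarioConfig(rho=0.2, n_causal=8, n_noise=0, or_model=orx,
                                 n_cases=400, n_controls=401)
            for rep in range(25):
                d = sample_case_control(cfg, seed=1000 + rep)
                res = ntr_region_test(d.region, d.phenotype, n_perm=300,
                                      seed=rep)
                hits[orx] += res.p < 0.05
        assert hits[2.5] > hits[1.2]


class TestFDR:
    def test_single_region_q_equals_p(self, small_simulated):
        res = ntr_region_test(small_simulated.region, small_simulated.phenotype,
                              n_perm=200, seed=3)
        study = fdr_adjust([res])
        assert study.regions[0].q == pytest.approx(res.p)

    def test_bh_step_up_by_hand(self):
        results = [
            _dummy_result(f"g{i}", p)
            for i, p in enumerate((0.01, 0.02, 0.03, 0.04))
        ]
        study = fdr_adjust(results)
        for r in study.regions:
            assert r.q == pytest.approx(0.04)

    def test_all_ones(self):
        study = fdr_adjust([_dummy_result("a", 1.0), _dummy_result("b", 1.0)])
        assert all(r.q == 1.0 for r in study.regions)

    def test_q_at_least_p_and_bh_min_helper(self):
        assert _bh_adjusted_min(np.array([0.01, 0.5, 0.6])) == pytest.approx(0.03)
        study = fdr_adjust(
            [_dummy_result(str(i), p) for i, p in enumerate((0.3, 0.01, 0.9))]
        )
        for r in study.regions:
            assert r.q >= r.p - 1e-12


def _dummy_result(region_id, p):
    from ntrtest.ntr import RegionTestResult

    return RegionTestResult(
        region_id=region_id, r=np.zeros(3), m=np.zeros(3), s=np.ones(3),
        z=np.zeros(3), k_star=1, p=p, n_perm=0,
    )
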