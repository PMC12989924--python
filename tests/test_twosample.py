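"""L1 statistic, permutation tests and weighted-logrank comparators."""

import math

import numpy as np
import pytest

from cgtree import (
    ClaytonCopula,
    IndependenceCopula,
    SurvivalSample,
    TwoSampleData,
    exhaustive_permutation_test,
    kaplan_meier,
    l1_statistic,
    n_distinct_assignments,
    permutation_test,
    weighted_logrank,
)
from cgtree.twosample import permutation_test_multi

from conftest import random_two_sample


class TestL1Statistic:
    def test_identical_groups_zero(self):
        g = SurvivalSample([1, 2, 3, 4], [1, 0, 1, 1])
        l1, l1s = l1_statistic(TwoSampleData(g, g), IndependenceCopula())
        assert l1 == 0.0
        assert l1s == 0.0

    def test_group_swap_antisymmetry(self, small_two_sample):
        d = small_two_sample
        cop = ClaytonCopula(2.0)
        l1, l1s = l1_statistic(d, cop)
        swapped = TwoSampleData(d.group2, d.group1)
        l1b, l1sb = l1_statistic(swapped, cop)
        assert l1b == pytest.approx(l1, abs=1e-14)
        assert l1sb == pytest.approx(-l1s, abs=1e-14)

    def test_signed_bounded_by_absolute(self, rng):
        cop = ClaytonCopula(2.0)
        for _ in range(20):
            d = random_two_sample(rng, 10, 12, shift=float(rng.uniform(0.5, 2)))
            l1, l1s = l1_statistic(d, cop)
            assert abs(l1s) <= l1 + 1e-14

    @pytest.mark.parametrize("family_tau", [("independence", 0.0), ("clayton", 0.5)])
    def test_fine_grid_integration_oracle(self, rng, family_tau):
        """Exact piecewise integration equals brute-force Riemann sums."""
        from cgtree import archimedean_copula, copula_graphic

        cop = archimedean_copula(*family_tau)
        for _ in range(5):
            d = random_two_sample(rng, 8, 10, shift=1.5, tie_prob=0.3)
            l1, l1s = l1_statistic(d, cop)
            tstar = min(d.group1.x.max(), d.group2.x.max())
            grid = np.linspace(0, tstar, 100_001)[:-1]  # left endpoints
            s1 = copula_graphic(d.group1, cop)(grid, clip=True)
            s2 = copula_graphic(d.group2, cop)(grid, clip=True)
            oracle = np.abs(s1 - s2).mean()  # already normalized by tstar
            oracle_signed = (s1 - s2).mean()
            assert l1 == pytest.approx(oracle, abs=1e-3)
            assert l1s == pytest.approx(oracle_signed, abs=1e-3)

    def test_printed_km_example(self):
        """x1=(1,2,3), x2=(2,4,6), all events, independence: the exact
        integral of |KM1-KM2|/t* over [0, 3]."""
        d = TwoSampleData(
            SurvivalSample([1, 2, 3], [1, 1, 1]),
            SurvivalSample([2, 4, 6], [1, 1, 1]),
        )
        l1, l1s = l1_statistic(d, IndependenceCopula())
        # segments: [1,2): |2/3-1|=1/3 ; [2,3): |1/3-2/3|=1/3  => (2/3)/3
        assert l1 == pytest.approx(2 / 9, abs=1e-12)
        assert l1s == pytest.approx(-2 / 9, abs=1e-12)

    def test_degenerate_tstar_rejected(self):
        d = TwoSampleData(
            SurvivalSample([0.0], [1]), SurvivalSample([1.0], [1])
        )
        with pytest.raises(ValueError):
            l1_statistic(d, IndependenceCopula())


class TestPermutationTest:
    def test_p_at_least_one_over_nperm(self, rng):
        d = random_two_sample(rng, 5, 5, shift=10.0)
        res = permutation_test(d, IndependenceCopula(), nperm=100, seed=1)
        assert res.p_value >= 1 / 100

    def test_nperm_validation(self, small_two_sample):
        with pytest.raises(ValueError):
            permutation_test(small_two_sample, IndependenceCopula(), nperm=1)

    def test_deterministic_given_seed(self, small_two_sample):
        cop = ClaytonCopula(2.0)
        r1 = permutation_test(small_two_sample, cop, nperm=200, seed=5)
        r2 = permutation_test(small_two_sample, cop, nperm=200, seed=5)
        assert r1.p_value == r2.p_value
        assert r1.l1 == r2.l1

    def test_monte_carlo_close_to_exhaustive_tiny(self, rng):
        """n1=n2=3 with distinct values: C(6,3)=20 assignments enumerate the
        exact p-value; Monte Carlo with nperm=20000 is within 0.02."""
        d = TwoSampleData(
            SurvivalSample([1.0, 2.0, 3.0], [1, 1, 1]),
            SurvivalSample([1.5, 4.0, 6.0], [1, 0, 1]),
        )
        cop = IndependenceCopula()
        exact = exhaustive_permutation_test(d, cop)
        assert exact.nperm == 20
        mc = permutation_test(d, cop, nperm=20_000, seed=3)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_monte_carlo_within_3se_of_exhaustive(self, rng):
        """On datasets with C(n, n1) <= 5000, Monte-Carlo p lies within
        3 binomial SEs of the exhaustive p."""
        cop = ClaytonCopula(2.0)
        for _ in range(5):
            d = random_two_sample(rng, 6, 6, shift=1.5)  # C(12,6)=924
            exact = exhaustive_permutation_test(d, cop)
            nperm = 9240
            mc = permutation_test(d, cop, nperm=nperm, seed=11)
            se = math.sqrt(exact.p_value * (1 - exact.p_value) / nperm)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 1 / nperm

    def test_exhaustive_two_subjects(self):
        d = TwoSampleData(SurvivalSample([1.0], [1]), SurvivalSample([2.0], [1]))
        res = exhaustive_permutation_test(d, IndependenceCopula())
        assert res.nperm == 2
        assert res.p_value in (0.5, 1.0)

    def test_exhaustive_cap_refuses_large_problems(self, rng):
        d = random_two_sample(rng, 50, 50)
        assert n_distinct_assignments(50, 50) == 100891344545564193334812497256
        with pytest.raises(ValueError, match="cap"):
            exhaustive_permutation_test(d, IndependenceCopula())

    def test_scale_invariance(self, small_two_sample):
        """A common time rescaling leaves L1 and the p-value unchanged
        (the statistic is normalized by t*)."""
        d = small_two_sample
        cop = ClaytonCopula(2.0)
        r1 = permutation_test(d, cop, nperm=300, seed=9)
        scaled = TwoSampleData(
            SurvivalSample(d.group1.x * 37.5, d.group1.delta),
            SurvivalSample(d.group2.x * 37.5, d.group2.delta),
        )
        r2 = permutation_test(scaled, cop, nperm=300, seed=9)
        assert r2.l1 == pytest.approx(r1.l1, rel=1e-12)
        assert r2.p_value == r1.p_value

    def test_within_group_relabeling_invariance(self, rng):
        d = random_two_sample(rng, 7, 8)
        cop = IndependenceCopula()
        r1 = permutation_test(d, cop, nperm=300, seed=2)
        perm = rng.permutation(7)
        shuffled = TwoSampleData(
            SurvivalSample(d.group1.x[perm], d.group1.delta[perm]), d.group2
        )
        r2 = permutation_test(shuffled, cop, nperm=300, seed=2)
        assert r2.l1 == pytest.approx(r1.l1, abs=1e-14)
        assert r2.p_value == r1.p_value

    def test_multi_copula_shares_permutations(self, small_two_sample):
        cops = [IndependenceCopula(), ClaytonCopula(2.0)]
        multi = permutation_test_multi(small_two_sample, cops, 300, seed=4)
        single = permutation_test(small_two_sample, cops[0], 300, seed=4)
        assert multi[0].p_value == single.p_value


class TestWeightedLogrank:
    def test_identical_groups_large_p(self):
        g1 = SurvivalSample([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        g2 = SurvivalSample([1.01, 2.01, 3.01, 4.01, 5.01], [1, 1, 1, 1, 1])
        stat, p = weighted_logrank(TwoSampleData(g1, g2))
        assert p > 0.5

    def test_hand_computed_risk_table(self):
        """Two tiny groups, risk table worked out by an explicit per-time
        loop (independent of the vectorized implementation)."""
        g1 = SurvivalSample([1.0, 3.0, 5.0], [1, 0, 1])
        g2 = SurvivalSample([2.0, 4.0, 6.0], [1, 1, 0])
        x = np.concatenate([g1.x, g2.x])
        delta = np.concatenate([g1.delta, g2.delta])
        in1 = np.array([True] * 3 + [False] * 3)
        u = v = 0.0
        for t in sorted(x[delta == 1]):
            at = x >= t
            n_t, n1_t = at.sum(), (at & in1).sum()
            d_t = ((x == t) & (delta == 1)).sum()
            d1_t = ((x == t) & (delta == 1) & in1).sum()
            u += d1_t - d_t * n1_t / n_t
            if n_t > 1:
                v += (
                    d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
                )
        expected = u**2 / v
        stat, _ = weighted_logrank(TwoSampleData(g1, g2), "logrank")
        assert stat == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("weight,lifelines_kw", [
        ("logrank", {}), ("peto_peto", {"weightings": "peto"}),
    ])
    def test_against_lifelines(self, rng, weight, lifelines_kw):
        from lifelines.statistics import logrank_test

        for _ in range(100):
            d = random_two_sample(
                rng,
                int(rng.integers(5, 25)),
                int(rng.integers(5, 25)),
                shift=float(rng.uniform(0.5, 2.0)),
                tie_prob=0.3,
            )
            try:
                stat, p = weighted_logrank(d, weight)
            except ValueError:
                continue  # degenerate (no events / zero variance)
            ref = logrank_test(
                d.group1.x,
                d.group2.x,
                event_observed_A=d.group1.delta,
                event_observed_B=d.group2.delta,
                **lifelines_kw,
            )
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_zero_events_rejected(self):
        d = TwoSampleData(
            SurvivalSample([1, 2], [0, 0]), SurvivalSample([3, 4], [0, 0])
        )
        with pytest.raises(ValueError):
            weighted_logrank(d)
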