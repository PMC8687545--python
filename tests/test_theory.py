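"""Closed-form MSD theory: stationary law, displacement algebra, AMSD, bounds."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from centroidmsd import (
    OutreachDistribution,
    SequentialConfiguration,
    UnequalWeightsError,
    amsd,
    attach_displacement,
    attach_expectation,
    build_sequential_state,
    detach_possibilities,
    detach_sum_expectation,
    exact_msd_small_n,
    lower_bound,
    mean_jump,
    msd_of_tau,
    outreach_mean_square,
    sequential_path_probability,
    stationary_distribution,
    switch_probability,
)

E2 = 100 / 3  # E[|eta|^2] of the default outreach law
R_GRID = [Fraction(1, 4), Fraction(1, 2), Fraction(1), Fraction(2), Fraction(10), Fraction(100)]


class TestSwitchProbability:
    def test_balanced_ratio_gives_one_over_n(self):
        for k in range(6):
            assert switch_probability(5, 1.0, k) == pytest.approx(0.2)

    def test_attach_from_empty_is_one_over_n(self):
        for r in (0.01, 1.0, 1e4):
            assert r * switch_probability(5, r, 0) == pytest.approx(1 / 5)

    def test_two_site_attach_odds(self):
        for r in (0.25, 1.0, 7.0):
            assert r * switch_probability(2, r, 1) == pytest.approx(r / (1 + r))

    def test_normalization_is_exact_for_rationals(self):
        for n in range(1, 13):
            for r in R_GRID:
                for k in range(n + 1):
                    p = switch_probability(n, r, k)
                    assert k * p + (n - k) * r * p == 1

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            switch_probability(4, 1.0, 5)


class TestStationaryDistribution:
    def test_two_sites_symmetric(self):
        np.testing.assert_allclose(stationary_distribution(2, 1.0), [0.25, 0.5, 0.25])

    def test_five_sites_binomial(self):
        np.testing.assert_allclose(
            stationary_distribution(5, 1.0), np.array([1, 5, 10, 10, 5, 1]) / 32
        )

    def test_fully_attached_probability(self):
        for r in (0.25, 1.0, 3.0, 50.0):
            pi = stationary_distribution(5, r)
            assert pi[5] == pytest.approx(r**4 / (2 * (1 + r) ** 4))

    def test_normalization_and_detailed_balance_exact(self):
        for n in (1, 2, 5, 8, 12):
            for r in R_GRID:
                pi = stationary_distribution(n, r)
                assert sum(pi) == 1
                for k in range(n):
                    lhs = pi[k] * (n - k) * r * switch_probability(n, r, k)
                    rhs = pi[k + 1] * (k + 1) * switch_probability(n, r, k + 1)
                    assert lhs == rhs

    def test_aggregate_detach_probability_is_half(self):
        for n in (2, 5, 9):
            for r in R_GRID:
                pi = stationary_distribution(n, r)
                s = sum(pi[k] * k * switch_probability(n, r, k) for k in range(1, n + 1))
                assert s == Fraction(1, 2)


class TestMeanJump:
    def test_single_site_is_half_mean_outreach(self, default_dist):
        for r in (0.25, 1.0, 10.0):
            np.testing.assert_allclose(
                mean_jump(1, r, default_dist), default_dist.mean_vector() / 2
            )

    def test_two_sites_balanced(self, default_dist):
        np.testing.assert_allclose(
            mean_jump(2, 1.0, default_dist), [45 / (8 * math.pi), 0.0], atol=1e-14
        )

    def test_isotropic_outreach_has_no_drift(self, isotropic_dist):
        for n, r in [(3, 0.5), (7, 2.0)]:
            np.testing.assert_allclose(
                mean_jump(n, r, isotropic_dist), [0.0, 0.0], atol=1e-14
            )

    def test_unequal_weights_rejected(self, default_dist):
        with pytest.raises(UnequalWeightsError):
            mean_jump(3, 1.0, default_dist, weights=[1.0, 2.0, 1.0])


class TestDisplacementAlgebra:
    def test_attach_displacement_examples(self):
        np.testing.assert_allclose(attach_displacement(1, (2, 3)), [2, 3])
        np.testing.assert_allclose(attach_displacement(2, (1, 0)), [0.5, 0])
        np.testing.assert_allclose(attach_displacement(5, (5, 0)), [1, 0])

    def test_two_site_detach_is_plus_minus_half_eta(self):
        out = detach_possibilities(SequentialConfiguration([(1.0, 0.0)]))
        np.testing.assert_allclose(out, [[0.5, 0.0], [-0.5, 0.0]])

    def test_three_site_detach_coordinates(self):
        cfg = SequentialConfiguration([(1.0, 0.0), (0.0, 1.0)])
        out = detach_possibilities(cfg)
        np.testing.assert_allclose(
            out, [[0.25, 1 / 6], [-0.25, 1 / 6], [0.0, -1 / 3]], atol=1e-15
        )

    def test_five_site_detach_matches_tabulated_entries(self, rng):
        """The five displacement formulas for a detaching 5-FA sequential state."""
        e2, e3, e4, e5 = rng.normal(size=(4, 2))
        out = detach_possibilities(SequentialConfiguration([e2, e3, e4, e5]))
        expected = [
            (e2 / 2 + e3 / 3 + e4 / 4 + e5 / 5) / 4,
            (-e2 / 2 + e3 / 3 + e4 / 4 + e5 / 5) / 4,
            (-2 * e3 / 3 + e4 / 4 + e5 / 5) / 4,
            (-3 * e4 / 4 + e5 / 5) / 4,
            -e5 / 5,
        ]
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_detach_needs_two_sites(self):
        with pytest.raises(ValueError):
            detach_possibilities(SequentialConfiguration(np.empty((0, 2))))

    @given(
        etas=arrays(float, (9, 2), elements=st.floats(-20, 20)),
        k=st.integers(2, 10),
    )
    def test_algebra_matches_geometric_rebuild(self, etas, k):
        """Each possibility equals (c_k - v_d)/(k-1) from the realized geometry."""
        cfg = SequentialConfiguration(etas[: k - 1])
        state = build_sequential_state(cfg)
        for d, pred in enumerate(detach_possibilities(cfg)):
            keep = [i for i in range(k) if i != d]
            delta = state.v[keep].mean(axis=0) - state.c
            np.testing.assert_allclose(pred, delta, atol=1e-12)

    def test_build_sequential_state_examples(self):
        s1 = build_sequential_state(SequentialConfiguration(np.empty((0, 2))))
        np.testing.assert_allclose(s1.c, s1.v[0])
        s2 = build_sequential_state(SequentialConfiguration([(1.0, 0.0)]))
        np.testing.assert_allclose(s2.c, [0.5, 0.0])
        s3 = build_sequential_state(SequentialConfiguration([(1.0, 0.0), (0.0, 1.0)]))
        np.testing.assert_allclose(s3.c, [0.5, 1 / 3])
        assert s3.force_balance_residual() < 1e-12


class TestConfigurationExpectations:
    def test_attach_expectation_values(self, default_dist):
        assert attach_expectation(1, default_dist) == pytest.approx(E2)
        assert attach_expectation(2, default_dist) == pytest.approx(25 / 3)
        vals = [attach_expectation(k, default_dist) for k in range(1, 30)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_detach_sum_two_sites(self, default_dist):
        assert detach_sum_expectation(2, default_dist) == pytest.approx(50 / 3)

    def test_detach_sum_three_sites(self, isotropic_dist):
        assert detach_sum_expectation(3, isotropic_dist) == pytest.approx(7 / 24 * E2)

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_detach_sum_matches_monte_carlo(self, k, isotropic_dist, rng):
        """Mean-zero outreach: the closed form equals the brute-force sum."""
        totals = []
        for _ in range(5_000):
            etas = np.array([isotropic_dist.sample(rng) for _ in range(k - 1)])
            poss = detach_possibilities(SequentialConfiguration(etas))
            totals.append(sum(float(p @ p) for p in poss))
        totals = np.asarray(totals)
        se = totals.std(ddof=1) / math.sqrt(len(totals))
        assert abs(totals.mean() - detach_sum_expectation(k, isotropic_dist)) < 4 * se


class TestAmsd:
    def test_single_site(self, default_dist):
        for r in (0.1, 1.0, 30.0):
            assert amsd(1, r, default_dist) == pytest.approx(E2 / 2)

    def test_two_sites_balanced(self, default_dist):
        assert amsd(2, 1.0, default_dist) == pytest.approx(12.5)

    def test_matches_exact_enumeration_for_two_sites(self, default_dist):
        for r in (0.1, 0.25, 1.0, 2.0, 10.0, 100.0):
            assert amsd(2, r, default_dist) == pytest.approx(
                exact_msd_small_n(2, r, default_dist), rel=1e-14
            )

    def test_exact_small_n_values(self, default_dist):
        assert exact_msd_small_n(1, 5.0, default_dist) == pytest.approx(50 / 3)
        assert exact_msd_small_n(2, 1.0, default_dist) == pytest.approx(12.5)
        # r -> 0 collapses to the single-site value
        assert exact_msd_small_n(2, 1e-12, default_dist) == pytest.approx(E2 / 2)
        with pytest.raises(ValueError):
            exact_msd_small_n(3, 1.0, default_dist)

    def test_unequal_weights_rejected(self, default_dist):
        with pytest.raises(UnequalWeightsError):
            amsd(4, 1.0, default_dist, weights=[1, 1, 2, 1])


class TestSequentialPathProbability:
    def test_examples(self):
        assert sequential_path_probability(5, 1.0, 1) == pytest.approx(1 / 160)
        assert sequential_path_probability(2, 1.0, 2) == pytest.approx(1 / 8)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            sequential_path_probability(5, 1.0, 0)

    def test_small_r_limit(self):
        for n in (2, 5, 9):
            assert sequential_path_probability(n, 1e-8, 1) == pytest.approx(0.5, abs=1e-6)
            for k in range(2, n + 1):
                assert sequential_path_probability(n, 1e-8, k) < 1e-6

    def test_large_r_limit(self):
        assert max(sequential_path_probability(5, 1e8, k) for k in range(1, 6)) < 1e-6


class TestLowerBound:
    def test_two_sites_balanced(self, default_dist):
        assert lower_bound(2, 1.0, default_dist) == pytest.approx(125 / 12 + 25 / 24)

    def test_single_site_reduces_to_attach_only(self, default_dist):
        for r in (0.5, 1.0, 4.0):
            assert lower_bound(1, r, default_dist) == pytest.approx(E2 / 2)

    def test_never_exceeds_amsd(self, default_dist):
        for n in range(1, 11):
            for r in (0.25, 0.5, 1.0, 2.0, 10.0, 100.0):
                assert lower_bound(n, r, default_dist) <= amsd(n, r, default_dist) + 1e-12


class TestMsdOfTau:
    def test_reduces_to_amsd_at_lag_one(self, default_dist):
        for n, r in [(2, 1.0), (5, 0.25), (8, 10.0)]:
            assert msd_of_tau(n, r, default_dist, 1) == pytest.approx(amsd(n, r, default_dist))

    def test_two_site_quadratic_value(self, default_dist):
        m2 = (45 / (8 * math.pi)) ** 2
        assert msd_of_tau(2, 1.0, default_dist, 2) == pytest.approx(2 * 12.5 + 2 * m2)

    def test_isotropic_outreach_is_linear_in_tau(self, isotropic_dist):
        a = amsd(5, 1.0, isotropic_dist)
        for tau in (1, 3, 10, 50):
            assert msd_of_tau(5, 1.0, isotropic_dist, tau) == pytest.approx(tau * a)

    def test_rejects_nonpositive_lag(self, default_dist):
        with pytest.raises(ValueError):
            msd_of_tau(2, 1.0, default_dist, 0)
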