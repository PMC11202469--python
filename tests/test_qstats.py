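"""Tsallis entropy, q-JSD disequilibrium, and statistical complexity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tipeplane import (
    PatternDistribution,
    disequilibrium,
    entropy_complexity_curve,
    max_q_jsd,
    max_tsallis_entropy,
    normalized_tipe,
    q_jsd,
    q_log,
    statistical_complexity,
    tsallis_entropy,
)
from oracles import naive_q_jsd, shannon_entropy, shannon_jsd

Q_SAMPLES = [0.0, 0.5, 1.0, 2.0, 10.0, 100.0]


def random_distribution(rng, n, sparse=False):
    p = rng.dirichlet(np.full(n, 0.5 if sparse else 1.0))
    if sparse:
        p[p < 0.02] = 0.0
        p /= p.sum()
    return p


class TestQLog:
    def test_shannon_branch_at_q_one(self):
        assert q_log(math.e, 1.0) == pytest.approx(1.0, abs=1e-14)

    def test_unit_argument_is_zero_for_any_q(self):
        for q in Q_SAMPLES:
            assert q_log(1.0, q) == pytest.approx(0.0, abs=1e-14)

    def test_q_zero_reduces_to_x_minus_one(self):
        assert q_log(3.0, 0.0) == pytest.approx(2.0, abs=1e-14)

    def test_nonpositive_argument_rejected(self):
        with pytest.raises(ValueError):
            q_log(0.0, 2.0)

    def test_continuous_through_q_equals_one(self):
        for x in [0.25, 2.0, 17.0]:
            left = q_log(x, 1.0 - 1e-6)
            right = q_log(x, 1.0 + 1e-6)
            assert left == pytest.approx(math.log(x), abs=1e-4)
            assert right == pytest.approx(math.log(x), abs=1e-4)


class TestTsallisEntropy:
    @pytest.mark.parametrize("q", Q_SAMPLES)
    def test_uniform_attains_q_log_of_state_count(self, q):
        P = PatternDistribution.uniform(16)
        assert tsallis_entropy(P, q) == pytest.approx(q_log(16.0, q), rel=1e-12)

    @pytest.mark.parametrize("q", Q_SAMPLES)
    def test_point_mass_has_zero_entropy(self, q):
        assert tsallis_entropy(PatternDistribution.delta(16), q) == 0.0

    def test_shannon_limit_on_fair_coin(self):
        assert tsallis_entropy(np.array([0.5, 0.5]), 1.0) == pytest.approx(
            math.log(2), abs=1e-14
        )

    def test_agrees_with_shannon_oracle_at_q_one(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = random_distribution(rng, rng.integers(2, 30))
            assert tsallis_entropy(p, 1.0) == pytest.approx(
                shannon_entropy(p), abs=1e-10
            )

    def test_continuity_into_the_shannon_branch(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = random_distribution(rng, 12)
            for q in (1.0 - 1e-6, 1.0 + 1e-6):
                assert abs(tsallis_entropy(p, q) - shannon_entropy(p)) <= 1e-4


class TestNormalizedEntropy:
    def test_limits(self):
        for q in Q_SAMPLES:
            assert normalized_tipe(PatternDistribution.uniform(9), q) == pytest.approx(1.0)
            assert normalized_tipe(PatternDistribution.delta(9), q) == 0.0

    def test_binary_shannon_oracle(self):
        h = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25)) / math.log(2)
        assert normalized_tipe(np.array([0.75, 0.25]), 1.0) == pytest.approx(h, abs=1e-12)
        assert h == pytest.approx(0.8113, abs=5e-5)

    def test_single_state_normalizer_rejected(self):
        with pytest.raises(ValueError):
            max_tsallis_entropy(1, 2.0)


class TestQJsd:
    def test_vanishes_on_identical_arguments(self):
        u = PatternDistribution.uniform(8)
        for q in Q_SAMPLES:
            assert q_jsd(u, u, q) == pytest.approx(0.0, abs=1e-14)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(21)
        p, r = random_distribution(rng, 6), random_distribution(rng, 6)
        for q in [0.0, 0.5, 1.0, 3.0]:
            assert q_jsd(p, r, q) == pytest.approx(q_jsd(r, p, q), rel=1e-12)

    def test_equals_classical_jsd_at_q_one(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            p = random_distribution(rng, 4, sparse=True)
            u = np.full(4, 0.25)
            assert q_jsd(p, u, 1.0) == pytest.approx(shannon_jsd(p, u), abs=1e-12)

    def test_matches_scalar_loop_oracle_across_q(self):
        rng = np.random.default_rng(23)
        for q in [0.0, 0.3, 1.0, 2.5, 40.0]:
            p = random_distribution(rng, 10, sparse=True)
            u = np.full(10, 0.1)
            assert q_jsd(p, u, q) == pytest.approx(naive_q_jsd(p, u, q), rel=1e-10)

    def test_mismatched_state_counts_rejected(self):
        with pytest.raises(ValueError):
            q_jsd(np.full(4, 0.25), np.full(5, 0.2), 1.0)


class TestMaxQJsd:
    def test_classical_value_for_two_states(self):
        expected = shannon_jsd([1.0, 0.0], [0.5, 0.5])
        assert max_q_jsd(2, 1.0) == pytest.approx(expected, abs=1e-12)

    def test_independent_of_which_state_carries_the_mass(self):
        for q in [0.5, 1.0, 2.0]:
            u = np.full(6, 1 / 6)
            vals = {
                round(q_jsd(PatternDistribution.delta(6, i), u, q), 14)
                for i in range(6)
            }
            assert len(vals) == 1
            assert vals.pop() == pytest.approx(max_q_jsd(6, q), rel=1e-12)

    @pytest.mark.parametrize("q", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [2, 4, 16])
    def test_point_mass_maximizes_over_sampled_distributions(self, n, q):
        """Brute-force search never beats the point-mass normalizer."""
        rng = np.random.default_rng(1000 * n + int(10 * q))
        u = np.full(n, 1.0 / n)
        star = max_q_jsd(n, q)
        for _ in range(300):
            p = random_distribution(rng, n, sparse=bool(rng.integers(2)))
            assert q_jsd(p, u, q) <= star + 1e-9
        # greedy refinement around the best two-level candidate
        for a in np.linspace(0.5, 1.0, 101)[:-1]:
            p = np.full(n, (1 - a) / (n - 1))
            p[0] = a
            assert q_jsd(p, u, q) <= star + 1e-9


class TestDisequilibriumAndComplexity:
    def test_uniform_and_point_mass_extremes(self):
        for q in Q_SAMPLES:
            assert disequilibrium(PatternDistribution.uniform(12), q) == pytest.approx(
                0.0, abs=1e-12
            )
            assert disequilibrium(PatternDistribution.delta(12), q) == pytest.approx(
                1.0, rel=1e-12
            )

    def test_ratio_matches_shannon_oracle_at_q_one(self):
        rng = np.random.default_rng(31)
        p = random_distribution(rng, 4)
        u = np.full(4, 0.25)
        expected = shannon_jsd(p, u) / shannon_jsd([1, 0, 0, 0], u)
        assert disequilibrium(p, 1.0) == pytest.approx(expected, rel=1e-10)

    def test_complexity_vanishes_at_both_order_extremes(self):
        for q in Q_SAMPLES:
            assert statistical_complexity(PatternDistribution.uniform(8), q).Cq == (
                pytest.approx(0.0, abs=1e-12)
            )
            assert statistical_complexity(PatternDistribution.delta(8), q).Cq == 0.0

    def test_point_reports_consistent_product(self):
        rng = np.random.default_rng(32)
        p = random_distribution(rng, 16, sparse=True)
        pt = statistical_complexity(p, 2.5)
        assert pt.Cq == pytest.approx(pt.delta_q * pt.Hq, rel=1e-14)
        assert pt.delta_q == pytest.approx(pt.Dq / pt.Dq_star, rel=1e-14)

    @given(
        seed=st.integers(0, 2**20),
        n=st.sampled_from([2, 8, 64, 1024]),
        q=st.floats(0.0, 100.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_hold_for_random_distributions(self, seed, n, q):
        """H_q, Delta_q and C_q stay inside [0, 1] and finite over the q range."""
        p = random_distribution(np.random.default_rng(seed), n)
        pt = statistical_complexity(p, q)
        for value in (pt.Hq, pt.delta_q, pt.Cq):
            assert np.isfinite(value)
            assert -1e-12 <= value <= 1.0 + 1e-9

    def test_finite_for_extreme_probabilities(self):
        """Numerical contract: q up to 100 with probabilities down to 1e-6."""
        p = np.full(10, 1e-6)
        p[0] = 1.0 - 9e-6
        for q in [0.0, 1.0, 50.0, 100.0]:
            pt = statistical_complexity(p, q)
            assert np.isfinite(pt.Hq) and np.isfinite(pt.Cq)


class TestVectorizedCurve:
    def test_matches_scalar_computation_pointwise(self):
        rng = np.random.default_rng(41)
        p = random_distribution(rng, 81, sparse=True)
        grid = np.array([0.0, 0.5, 0.999999999, 1.0, 1.5, 7.0, 100.0])
        curve = entropy_complexity_curve(p, grid)
        for i, q in enumerate(grid):
            pt = statistical_complexity(p, q)
            assert curve.Hq[i] == pytest.approx(pt.Hq, abs=1e-12)
            assert curve.Cq[i] == pytest.approx(pt.Cq, abs=1e-12)

    def test_uniform_distribution_gives_flat_extremal_curve(self):
        grid = np.linspace(0, 100, 201)
        curve = entropy_complexity_curve(PatternDistribution.uniform(16), grid)
        np.testing.assert_allclose(curve.Hq, 1.0, atol=1e-12)
        np.testing.assert_allclose(curve.Cq, 0.0, atol=1e-12)

    def test_rejects_negative_q(self):
        with pytest.raises(ValueError):
            entropy_complexity_curve(PatternDistribution.uniform(4), np.array([-1.0]))
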