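import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renyifs import (
    BinningRule,
    DiscreteDistribution,
    JointDistribution,
    apply_binning,
    bayes_risk,
    conditional_min_entropy,
    estimate_joint,
    fit_binning,
    min_entropy,
    min_entropy_mutual_information,
    renyi_entropy,
    shannon_conditional_entropy,
    shannon_entropy,
    shannon_mutual_information,
)
from conftest import random_joint

J_EXAMPLE = JointDistribution(np.array([[0.4, 0.1], [0.2, 0.3]]))


def dist(*p):
    return DiscreteDistribution(np.array(p, dtype=float))


@st.composite
def distributions(draw, max_outcomes=8):
    n = draw(st.integers(2, max_outcomes))
    w = draw(st.lists(st.floats(1e-3, 1.0), min_size=n, max_size=n))
    p = np.array(w) / np.sum(w)
    return DiscreteDistribution(p / p.sum())


class TestBinning:
    def test_equal_frequency_quartiles(self):
        X = np.arange(1, 101, dtype=float)[:, None]
        rule = fit_binning(X, BinningRule("equal-frequency", 4))
        codes = apply_binning(X, rule)
        assert np.bincount(codes[:, 0]).tolist() == [25, 25, 25, 25]

    def test_equal_width_two_bins(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        rule = fit_binning(X, BinningRule("equal-width", 2))
        np.testing.assert_allclose(rule.edges_[0], [1.5])
        assert np.bincount(apply_binning(X, rule)[:, 0]).tolist() == [2, 2]

    def test_constant_feature_warns_and_collapses(self):
        X = np.full((10, 1), 2.5)
        with pytest.warns(UserWarning, match="constant"):
            rule = fit_binning(X, BinningRule(n_bins=4))
        assert np.all(apply_binning(X, rule) == 0)

    def test_out_of_range_values_clip_to_extreme_bins(self):
        rule = fit_binning(np.arange(10.0)[:, None], BinningRule(n_bins=2))
        codes = apply_binning(np.array([[-100.0], [100.0]]), rule)
        assert codes[:, 0].tolist() == [0, 1]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            BinningRule(n_bins=1)


class TestJointEstimation:
    def test_perfect_association(self):
        j = estimate_joint(np.array([0, 0, 1, 1]), np.array([[0], [0], [1], [1]]))
        np.testing.assert_allclose(j.probs, [[0.5, 0], [0, 0.5]])

    def test_independent_uniform(self):
        y = np.array([0, 0, 1, 1])
        S = np.array([[0], [1], [0], [1]])
        j = estimate_joint(y, S, sparse_warn=False)
        np.testing.assert_allclose(j.probs, 0.25)

    def test_two_column_hand_tally(self):
        # 8 explicit rows; occupied product cells counted by hand
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        S = np.array([[0, 0], [0, 0], [0, 1], [1, 0],
                      [1, 0], [1, 1], [1, 1], [1, 1]])
        j = estimate_joint(y, S, sparse_warn=False)
        cells = {tuple(c): i for i, c in enumerate(j.y_labels)}
        assert j.probs[0, cells[(0, 0)]] == pytest.approx(2 / 8)
        assert j.probs[0, cells[(0, 1)]] == pytest.approx(1 / 8)
        assert j.probs[0, cells[(1, 0)]] == pytest.approx(1 / 8)
        assert j.probs[1, cells[(1, 0)]] == pytest.approx(1 / 8)
        assert j.probs[1, cells[(1, 1)]] == pytest.approx(3 / 8)
        assert (0, 1) in cells and len(cells) == 4  # (0,1) occupied, (1,1) too

    def test_sparse_joint_warns(self):
        y = np.arange(8) % 2
        S = np.arange(8)[:, None]
        with pytest.warns(UserWarning, match="sparse"):
            estimate_joint(y, S)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_joint(np.array([0, 1]), np.array([[0], [1], [0]]))


class TestRenyiFamily:
    @pytest.mark.parametrize("delta", [0.5, 2.0, 5.0, 100.0])
    def test_uniform_gives_log_n(self, delta):
        assert renyi_entropy(dist(*[0.25] * 4), delta) == pytest.approx(2.0)

    def test_collision_entropy_example(self):
        # H_2 = -log2 sum p^2 = -log2 0.375
        got = renyi_entropy(dist(0.5, 0.25, 0.25), 2.0)
        assert got == pytest.approx(-np.log2(0.375), abs=1e-10)
        assert got == pytest.approx(1.41504, abs=1e-5)

    def test_degenerate_distribution_zero_for_all_orders(self):
        for delta in (0.5, 2.0, 50.0):
            assert renyi_entropy(dist(1.0, 0.0), delta) == pytest.approx(0.0)

    def test_invalid_orders_rejected(self):
        d = dist(0.5, 0.5)
        with pytest.raises(ValueError):
            renyi_entropy(d, 1.0)
        with pytest.raises(ValueError):
            renyi_entropy(d, -2.0)

    def test_shannon_limit_bracketed(self):
        d = dist(0.5, 0.25, 0.25)
        h1 = shannon_entropy(d)
        lo = renyi_entropy(d, 1 + 1e-6)
        hi = renyi_entropy(d, 1 - 1e-6)
        assert lo <= h1 + 1e-4 <= hi + 2e-4
        assert abs(lo - h1) < 1e-4 and abs(hi - h1) < 1e-4

    def test_min_entropy_limit(self):
        # convergence from above at the exact theoretical rate:
        # 0 <= H_delta - H_inf <= H_inf / (delta - 1)
        for p in [dist(0.5, 0.25, 0.25), dist(0.7, 0.2, 0.1), dist(0.4, 0.3, 0.3)]:
            hinf = min_entropy(p)
            for delta in (10.0, 100.0, 1000.0):
                gap = renyi_entropy(p, delta) - hinf
                assert -1e-12 <= gap <= hinf / (delta - 1) + 1e-12
            assert abs(renyi_entropy(p, 1000.0) - hinf) < 1e-2

    @given(distributions())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_monotone_nonincreasing_in_delta(self, d):
        deltas = [0.5, 0.9, 1.5, 2.0, 5.0, 50.0]
        values = [renyi_entropy(d, x) for x in deltas]
        assert all(a >= b - 1e-10 for a, b in zip(values, values[1:]))

    @given(distributions())
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_family_bounded_by_shannon_and_min_entropy(self, d):
        h1, hinf = shannon_entropy(d), min_entropy(d)
        assert hinf <= h1 + 1e-10
        assert renyi_entropy(d, 2.0) <= h1 + 1e-10
        assert renyi_entropy(d, 2.0) >= hinf - 1e-10


class TestShannonQuantities:
    def test_fair_coin(self):
        assert shannon_entropy(dist(0.5, 0.5)) == pytest.approx(1.0)

    def test_min_entropy_of_half_max(self):
        assert min_entropy(dist(0.5, 0.25, 0.25)) == pytest.approx(1.0)

    def test_conditional_zero_when_determined(self):
        j = JointDistribution(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert shannon_conditional_entropy(j) == pytest.approx(0.0)

    def test_conditional_equals_marginal_when_independent(self):
        px, py = np.array([0.3, 0.7]), np.array([0.25, 0.75])
        j = JointDistribution(np.outer(px, py))
        hx = shannon_entropy(DiscreteDistribution(px))
        assert shannon_conditional_entropy(j) == pytest.approx(hx, abs=1e-12)
        assert shannon_mutual_information(j) == pytest.approx(0.0, abs=1e-12)

    def test_example_joint_by_brute_force(self):
        p = J_EXAMPLE.probs
        py = p.sum(axis=0)
        expected = -sum(p[x, y] * np.log2(p[x, y] / py[y])
                        for x in range(2) for y in range(2))
        assert shannon_conditional_entropy(J_EXAMPLE) == pytest.approx(expected, abs=1e-12)

    def test_identical_variables_one_bit(self):
        j = JointDistribution(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert shannon_mutual_information(j) == pytest.approx(1.0)

    def test_mi_symmetric_under_axis_swap(self):
        a = shannon_mutual_information(J_EXAMPLE)
        b = shannon_mutual_information(J_EXAMPLE.swap_axes())
        assert a == pytest.approx(b, abs=1e-12)


class TestMinEntropyQuantities:
    def test_conditional_min_entropy_example(self):
        # column maxima 0.4 and 0.3 -> -log2 0.7
        assert conditional_min_entropy(J_EXAMPLE) == pytest.approx(-np.log2(0.7), abs=1e-12)
        assert conditional_min_entropy(J_EXAMPLE) == pytest.approx(0.51457, abs=1e-5)

    def test_zero_when_determined(self):
        j = JointDistribution(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert conditional_min_entropy(j) == pytest.approx(0.0)
        assert bayes_risk(j) == pytest.approx(0.0)

    def test_equals_marginal_when_independent(self):
        px, py = np.array([0.6, 0.4]), np.array([0.2, 0.3, 0.5])
        j = JointDistribution(np.outer(px, py))
        assert conditional_min_entropy(j) == pytest.approx(
            min_entropy(DiscreteDistribution(px)), abs=1e-12)
        assert min_entropy_mutual_information(j) == pytest.approx(0.0, abs=1e-12)

    def test_bayes_risk_example(self):
        assert bayes_risk(J_EXAMPLE) == pytest.approx(0.3, abs=1e-12)

    def test_bayes_risk_uniform_independent(self):
        j = JointDistribution(np.full((4, 3), 1 / 12))
        assert bayes_risk(j) == pytest.approx(0.75)

    def test_min_entropy_mi_example_composes(self):
        hx = min_entropy(J_EXAMPLE.marginal_x())
        assert min_entropy_mutual_information(J_EXAMPLE) == pytest.approx(
            hx - conditional_min_entropy(J_EXAMPLE), abs=1e-12)

    def test_determined_uniform_4_gives_2_bits(self):
        j = JointDistribution(np.eye(4) / 4)
        assert min_entropy_mutual_information(j) == pytest.approx(2.0)


class TestRandomJointIdentities:
    """Identity suite over random strictly-positive joints."""

    def test_min_entropy_bayes_risk_link(self, rng):
        for _ in range(200):
            j = random_joint(rng, rng.integers(2, 5), rng.integers(2, 6))
            lhs = conditional_min_entropy(j)
            rhs = -np.log2(1 - bayes_risk(j))
            assert abs(lhs - rhs) <= 1e-10

    def test_chain_rule_identity(self, rng):
        for _ in range(100):
            j = random_joint(rng, 3, 4)
            h_joint = shannon_entropy(DiscreteDistribution(j.probs.ravel()))
            h_y = shannon_entropy(j.marginal_y())
            assert shannon_conditional_entropy(j) == pytest.approx(
                h_joint - h_y, abs=1e-10)

    def test_mutual_informations_nonnegative(self, rng):
        for _ in range(100):
            j = random_joint(rng, 3, 4)
            assert shannon_mutual_information(j) >= -1e-10
            assert min_entropy_mutual_information(j) >= -1e-10

    def test_conditioning_never_increases_min_entropy(self, rng):
        # H_inf(X | Y, Z) <= H_inf(X | Y) on empirical joints
        for _ in range(50):
            n = 200
            y = rng.integers(0, 3, n)
            YZ = rng.integers(0, 3, (n, 2))
            h_y = conditional_min_entropy(
                estimate_joint(y, YZ[:, :1], sparse_warn=False))
            h_yz = conditional_min_entropy(
                estimate_joint(y, YZ, sparse_warn=False))
            assert h_yz <= h_y + 1e-12

    def test_point_mass_and_uniform_anchors(self):
        point = dist(1.0, 0.0, 0.0)
        for fn in (shannon_entropy, min_entropy):
            assert fn(point) == pytest.approx(0.0)
        assert renyi_entropy(point, 3.0) == pytest.approx(0.0)
        unif = dist(*[1 / 8] * 8)
        assert shannon_entropy(unif) == pytest.approx(3.0)
        assert min_entropy(unif) == pytest.approx(3.0)
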