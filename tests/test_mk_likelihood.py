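import math

import numpy as np
import pytest

from mkasr.characters import CharacterColumn, to_partials
from mkasr.mk_likelihood import (
    LikelihoodError,
    PruningEngine,
    RateParameters,
    RootPrior,
    marginal_node_probs,
    mk_loglik,
    transition_matrix,
)
from mkasr.trees import parse_newick

from _oracles import enum_loglik, enum_marginal, random_binary_tree, random_partials


class TestRateParameters:
    def test_generator_rows_sum_to_zero(self):
        r = RateParameters(3, (0.1, 0.2, 0.3, 0.4, 0.5, 0.6))
        Q = r.generator()
        assert np.allclose(Q.sum(axis=1), 0.0)
        assert Q[0, 1] == 0.1 and Q[2, 1] == 0.6

    def test_negative_rate_rejected(self):
        with pytest.raises(LikelihoodError):
            RateParameters.binary(-0.1, 0.5)

    def test_stationary_distribution_binary(self):
        r = RateParameters.binary(0.3, 0.1)
        pi = r.stationary_distribution()
        assert pi == pytest.approx([0.25, 0.75])


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        for k, rates in [(2, (0.5, 1.2)), (3, (0.1,) * 6)]:
            P = transition_matrix(RateParameters(k, rates), 0.0)
            assert np.array_equal(P, np.eye(k))

    def test_symmetric_long_time_limit(self):
        P = transition_matrix(RateParameters.binary(1.0, 1.0), 50.0)
        assert np.allclose(P, 0.5, atol=1e-12)

    def test_binary_closed_form_value(self):
        # q01=q10=1, t=1: P00 = (1 + e^-2)/2
        P = transition_matrix(RateParameters.binary(1.0, 1.0), 1.0)
        assert P[0, 0] == pytest.approx((1 + math.exp(-2)) / 2, abs=1e-14)

    def test_rows_are_distributions(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 4))
            rates = RateParameters(k, tuple(rng.uniform(0, 3, k * (k - 1))))
            t = float(rng.uniform(0, 5))
            P = transition_matrix(rates, t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)

    def test_all_zero_generator_warns_identity(self):
        with pytest.warns(UserWarning):
            P = transition_matrix(RateParameters.binary(0.0, 0.0), 1.0)
        assert np.array_equal(P, np.eye(2))


class TestLoglik:
    def test_all_missing_is_log_one(self, rng):
        tree = random_binary_tree(8, rng)
        partials = {t.label: np.ones(2) for t in tree.tips()}
        ll = mk_loglik(tree, RateParameters.binary(0.7, 0.2), 1.3, partials)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_two_tip_closed_form(self):
        tree = parse_newick("(A:0.4,B:0.9);")
        q01, q10 = 0.8, 0.3
        rates = RateParameters.binary(q01, q10)
        partials = {"A": np.array([1.0, 0.0]), "B": np.array([1.0, 0.0])}
        P1 = transition_matrix(rates, 0.4)
        P2 = transition_matrix(rates, 0.9)
        expected = math.log(
            0.5 * (P1[0, 0] * P2[0, 0] + P1[1, 0] * P2[1, 0])
        )
        assert mk_loglik(tree, rates, 1.0, partials) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_enumeration_on_random_trees(self, k, rng):
        for _ in range(25):
            tree = random_binary_tree(int(rng.integers(2, 6)), rng)
            rates = RateParameters(k, tuple(rng.uniform(0.05, 2.0, k * (k - 1))))
            kappa = float(rng.uniform(0, 2))
            partials = random_partials(tree, k, rng)
            want = enum_loglik(tree, rates, kappa, partials, np.ones(k) / k)
            got = mk_loglik(tree, rates, kappa, partials)
            assert got == pytest.approx(want, abs=1e-8)

    def test_binary_fast_path_agrees_with_general_path(self, rng):
        tree = random_binary_tree(15, rng)
        partials = random_partials(tree, 2, rng)
        engine = PruningEngine(tree, partials, 2)
        for _ in range(10):
            q01, q10 = rng.uniform(0.05, 3.0, 2)
            kappa = float(rng.uniform(0, 3))
            fast = engine.loglik_binary(q01, q10, kappa)
            slow = engine.loglik(RateParameters.binary(q01, q10), kappa)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_state_relabeling_symmetry(self, rng):
        """Swapping 0<->1 in both data and rates leaves the likelihood
        unchanged."""
        for _ in range(10):
            tree = random_binary_tree(7, rng)
            q01, q10 = rng.uniform(0.05, 2.0, 2)
            partials = random_partials(tree, 2, rng)
            flipped = {t: v[::-1].copy() for t, v in partials.items()}
            ll = mk_loglik(tree, RateParameters.binary(q01, q10), 1.0, partials)
            llf = mk_loglik(tree, RateParameters.binary(q10, q01), 1.0, flipped)
            assert llf == pytest.approx(ll, abs=1e-10)

    def test_invariant_to_tip_order(self):
        a = parse_newick("((A:0.2,B:0.4):0.3,C:0.8);")
        b = parse_newick("(C:0.8,(B:0.4,A:0.2):0.3);")
        rates = RateParameters.binary(0.6, 0.25)
        partials = {
            "A": np.array([1.0, 0.0]),
            "B": np.array([0.0, 1.0]),
            "C": np.array([0.0, 1.0]),
        }
        assert mk_loglik(a, rates, 1.4, partials) == pytest.approx(
            mk_loglik(b, rates, 1.4, partials), abs=1e-12
        )

    def test_kappa_zero_ignores_branch_lengths(self, rng):
        """With kappa=0 every branch has unit length: the likelihood depends
        on topology only."""
        a = parse_newick("((A:0.2,B:0.4):0.3,C:0.8);")
        b = parse_newick("((A:2.0,B:0.01):1.3,C:0.08);")
        rates = RateParameters.binary(0.6, 0.25)
        partials = {
            "A": np.array([1.0, 0.0]),
            "B": np.array([0.0, 1.0]),
            "C": np.array([0.0, 1.0]),
        }
        assert mk_loglik(a, rates, 0.0, partials) == pytest.approx(
            mk_loglik(b, rates, 0.0, partials), abs=1e-12
        )


class TestMarginals:
    def test_tip_with_observed_state_is_degenerate(self):
        tree = parse_newick("((A:0.2,B:0.4):0.3,C:0.8);")
        partials = {
            "A": np.array([0.0, 1.0]),
            "B": np.array([1.0, 0.0]),
            "C": np.array([1.0, 0.0]),
        }
        tip = tree.tip_map()["A"]
        probs = marginal_node_probs(
            tree, RateParameters.binary(0.5, 0.5), 1.0, partials, node=tip
        )
        assert probs == pytest.approx([0.0, 1.0])

    def test_symmetric_case_gives_half_half_at_root(self):
        tree = parse_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);")
        partials = {
            "A": np.array([1.0, 0.0]),
            "B": np.array([1.0, 0.0]),
            "C": np.array([0.0, 1.0]),
            "D": np.array([0.0, 1.0]),
        }
        probs = marginal_node_probs(
            tree, RateParameters.binary(0.7, 0.7), 1.0, partials
        )
        assert probs == pytest.approx([0.5, 0.5], abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_enumeration_oracle(self, k, rng):
        for _ in range(20):
            tree = random_binary_tree(4, rng)
            rates = RateParameters(k, tuple(rng.uniform(0.05, 2.0, k * (k - 1))))
            kappa = float(rng.uniform(0, 2))
            partials = random_partials(tree, k, rng)
            internals = [n for n in tree.postorder() if not n.is_tip]
            node = internals[int(rng.integers(len(internals)))]
            want = enum_marginal(tree, rates, kappa, partials, np.ones(k) / k, node)
            got = marginal_node_probs(tree, rates, kappa, partials, node=node)
            assert np.abs(got - want).max() < 1e-10
            assert got.sum() == pytest.approx(1.0, abs=1e-10)

    def test_marginals_swap_under_relabeling(self, rng):
        tree = random_binary_tree(6, rng)
        partials = random_partials(tree, 2, rng)
        flipped = {t: v[::-1].copy() for t, v in partials.items()}
        p = marginal_node_probs(tree, RateParameters.binary(0.9, 0.2), 1.0, partials)
        pf = marginal_node_probs(tree, RateParameters.binary(0.2, 0.9), 1.0, flipped)
        assert pf == pytest.approx(p[::-1], abs=1e-10)


class TestRootPrior:
    def test_uniform_default(self):
        assert RootPrior.uniform(3).probabilities == pytest.approx([1 / 3] * 3)

    def test_must_sum_to_one(self):
        with pytest.raises(LikelihoodError):
            RootPrior((0.7, 0.7))

    def test_stationary_prior_matches_rates(self):
        prior = RootPrior.stationary(RateParameters.binary(0.9, 0.3))
        assert prior.probabilities == pytest.approx([0.25, 0.75])
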