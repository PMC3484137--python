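"""Rate matrices, transition probabilities, pruning, and marginals
against closed forms and the enumeration oracle."""

import numpy as np
import pytest

from traitcorr.ctmc import (BinaryRates, DependentRates, build_binary_matrix,
                            build_dependent_matrix, build_independent_matrix,
                            build_restricted_matrix, dual_tip_partials,
                            marginal_ancestral_probs, pruning_loglik,
                            stationary_distribution, transition_probabilities,
                            validate_rate_matrix)
from traitcorr.phylo import parse_newick

from helpers import (enum_loglik, enum_marginal, random_binary_q,
                     random_dependent_q, random_tip_partials, random_tree)


class TestRateMatrices:
    def test_independent_matrix_placement(self):
        Q = build_independent_matrix(BinaryRates(1, 2), BinaryRates(3, 4))
        # habitat transitions identical in both morphology backgrounds
        assert Q[0, 1] == 1 and Q[2, 3] == 1
        assert Q[1, 0] == 2 and Q[3, 2] == 2
        # morphology transitions identical in both habitat backgrounds
        assert Q[0, 2] == 3 and Q[1, 3] == 3
        assert Q[2, 0] == 4 and Q[3, 1] == 4
        assert np.allclose(Q.sum(axis=1), 0)
        assert Q[0, 3] == 0 and Q[1, 2] == 0

    def test_all_zero_rates_give_zero_matrix(self):
        Q = build_independent_matrix(BinaryRates(0, 0), BinaryRates(0, 0))
        assert np.all(Q == 0)

    def test_dependent_matrix_placement(self):
        r = DependentRates(q12=65.39, q13=57.17, q21=1, q24=2, q31=3,
                           q34=4, q42=5, q43=6)
        Q = build_dependent_matrix(r)
        assert Q[0, 1] == 65.39 and Q[0, 2] == 57.17
        assert Q[1, 3] == 2 and Q[3, 1] == 5
        assert Q[0, 3] == 0 and Q[3, 0] == 0 and Q[1, 2] == 0 and Q[2, 1] == 0

    def test_equal_rates_degenerate_to_independent(self):
        c = 1.7
        dep = build_dependent_matrix(DependentRates(*[c] * 8))
        ind = build_independent_matrix(BinaryRates(c, c), BinaryRates(c, c))
        assert np.allclose(dep, ind)

    def test_row_sums_zero_for_random_rates(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Q = random_dependent_q(rng)
            validate_rate_matrix(Q)

    def test_restricted_matrix_shares_gain_rate(self):
        r = DependentRates(q12=5, q13=5, q21=1, q24=1, q31=1, q34=1, q42=1, q43=1)
        Q = build_restricted_matrix(r)
        assert Q[0, 1] == 5 and Q[0, 2] == 5
        with pytest.raises(ValueError):
            build_restricted_matrix(DependentRates(q12=5, q13=4, q21=1, q24=1,
                                                   q31=1, q34=1, q42=1, q43=1))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            BinaryRates(-1, 1)
        with pytest.raises(ValueError):
            DependentRates(*([-0.1] + [1] * 7))


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self):
        Q = build_binary_matrix(BinaryRates(1, 2))
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(2))

    def test_two_state_closed_form(self):
        for a, b, t in [(1.0, 1.0, 1.0), (0.3, 2.1, 0.7), (5.0, 0.1, 2.0)]:
            P = transition_probabilities(build_binary_matrix(BinaryRates(a, b)), t)
            p01 = (a / (a + b)) * (1 - np.exp(-(a + b) * t))
            p10 = (b / (a + b)) * (1 - np.exp(-(a + b) * t))
            assert P[0, 1] == pytest.approx(p01, abs=1e-12)
            assert P[1, 0] == pytest.approx(p10, abs=1e-12)

    def test_matches_series_expansion(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            Q = random_dependent_q(rng)
            t = float(rng.uniform(0, 1.5))
            series = np.eye(4)
            term = np.eye(4)
            for n in range(1, 60):
                term = term @ (Q * t) / n
                series += term
            assert np.abs(transition_probabilities(Q, t) - series).max() < 1e-10

    def test_rows_sum_to_one_and_entries_in_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            Q = random_dependent_q(rng)
            P = transition_probabilities(Q, float(rng.uniform(0, 20)))
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
            assert P.min() >= 0 and P.max() <= 1 + 1e-12

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(build_binary_matrix(BinaryRates(1, 1)), -0.5)

    def test_defective_generator_falls_back(self):
        # symmetric equal-rate generator has repeated eigenvalues
        Q = build_dependent_matrix(DependentRates(*[1.0] * 8))
        P = transition_probabilities(Q, 0.8)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10


class TestPruningLoglik:
    def test_zero_branch_single_tip_uniform_root(self):
        tree = parse_newick("(A:0,B:0);")
        for k, Q in [(2, build_binary_matrix(BinaryRates(1, 1))),
                     (4, build_dependent_matrix(DependentRates(*[1.0] * 8)))]:
            ll = pruning_loglik(tree, {"A": 0, "B": 0}, Q)
            assert ll == pytest.approx(np.log(1.0 / k), abs=1e-12)

    def test_matches_enumeration_on_small_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            tree = random_tree(rng, int(rng.integers(2, 6)))
            for Q in (random_binary_q(rng), random_dependent_q(rng)):
                k = Q.shape[0]
                tips = random_tip_partials(rng, tree, k)
                root = np.full(k, 1.0 / k)
                got = pruning_loglik(tree, tips, Q, root=root)
                want = enum_loglik(tree, tips, Q, root)
                assert got == pytest.approx(want, abs=1e-10)

    def test_independent_model_factorises(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = random_tree(rng, 8)
            hab = {t: int(rng.integers(2)) if rng.random() > 0.2 else None
                   for t in tree.taxa}
            mor = {t: int(rng.integers(2)) if rng.random() > 0.2 else None
                   for t in tree.taxa}
            h_rates = BinaryRates(*rng.uniform(0.1, 2, 2))
            m_rates = BinaryRates(*rng.uniform(0.1, 2, 2))
            joint = pruning_loglik(tree, dual_tip_partials(hab, mor),
                                   build_independent_matrix(h_rates, m_rates))
            sep = (pruning_loglik(tree, hab, build_binary_matrix(h_rates)) +
                   pruning_loglik(tree, mor, build_binary_matrix(m_rates)))
            assert joint == pytest.approx(sep, abs=1e-10)

    def test_constraint_never_increases_likelihood(self):
        rng = np.random.default_rng(9)
        tree = random_tree(rng, 6)
        Q = random_binary_q(rng)
        tips = {t: int(rng.integers(2)) for t in tree.taxa}
        free = pruning_loglik(tree, tips, Q)
        node = tree.mrca(list(tree.taxa)[:3])
        probs = marginal_ancestral_probs(tree, tips, Q, node=node)
        best = int(np.argmax(probs))
        constrained = pruning_loglik(tree, tips, Q, constraints={node: {best}})
        assert constrained <= free + 1e-12

    def test_constrained_matches_enumeration(self):
        rng = np.random.default_rng(13)
        tree = random_tree(rng, 5)
        Q = random_binary_q(rng)
        tips = random_tip_partials(rng, tree, 2)
        node = tree.mrca(list(tree.taxa)[:2])
        root = np.array([0.5, 0.5])
        for s in (0, 1):
            got = pruning_loglik(tree, tips, Q, constraints={node: {s}})
            want = enum_loglik(tree, tips, Q, root, constraints={node: {s}})
            assert got == pytest.approx(want, abs=1e-10)

    def test_unknown_leaf_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        Q = build_binary_matrix(BinaryRates(1, 1))
        with pytest.raises(ValueError):
            pruning_loglik(tree, {"A": 0, "X": 1}, Q)
        with pytest.raises(ValueError):
            pruning_loglik(tree, {"A": 0}, Q)


class TestMarginalAncestralProbs:
    def test_observed_leaf_is_certain(self):
        tree = parse_newick("((A:1,B:1):1,C:1);")
        Q = build_binary_matrix(BinaryRates(1, 1))
        leaf = tree.leaf_index["A"]
        probs = marginal_ancestral_probs(tree, {"A": 1, "B": 0, "C": 0}, Q,
                                         node=leaf)
        assert probs[1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_enumeration_on_four_taxon_tree(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            tree = random_tree(rng, 4)
            for Q in (random_binary_q(rng), random_dependent_q(rng)):
                k = Q.shape[0]
                tips = random_tip_partials(rng, tree, k)
                node = tree.mrca(list(tree.taxa)[:2])
                got = marginal_ancestral_probs(tree, tips, Q, node=node)
                want = enum_marginal(tree, tips, Q, np.full(k, 1.0 / k), node)
                assert np.abs(got - want).max() < 1e-10
                assert got.sum() == pytest.approx(1.0, abs=1e-12)

    def test_short_branches_identical_tips_pin_state(self):
        tree = parse_newick("((A:1e-8,B:1e-8):1e-8,C:1e-8);")
        Q = build_binary_matrix(BinaryRates(1, 1))
        probs = marginal_ancestral_probs(tree, {"A": 1, "B": 1, "C": 1}, Q,
                                         node=tree.root)
        assert probs[1] > 0.9999


def test_stationary_distribution_solves_balance():
    rng = np.random.default_rng(2)
    Q = random_dependent_q(rng)
    pi = stationary_distribution(Q)
    assert np.abs(pi @ Q).max() < 1e-10
    assert pi.sum() == pytest.approx(1.0)
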