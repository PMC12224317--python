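"""Mk model: closed forms, pruning vs enumeration, rate recovery, counting."""

import itertools
import math
import random

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from faoclassify.ancestral_mk import (
    DEFAULT_STATES,
    PhyloCharacterSet,
    assign_max_probability_states,
    count_transitions,
    estimate_rate,
    label_internal_nodes,
    marginal_ancestral_probs,
    mk_log_likelihood,
    mk_transition_matrix,
)
from faoclassify.synth_data import gen_character_tree


def get_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


def brute_force(pcs, alpha):
    """Enumerate all internal-state assignments: likelihood and marginals."""
    k = pcs.k
    idx = {s: i for i, s in enumerate(pcs.states)}
    nodes = list(pcs.tree.preorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    margs = {n: np.zeros(k) for n in nodes}
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = 1.0 / k
        for n in nodes:
            if n.parent_node is None:
                continue
            ps = amap[n.parent_node]
            cs = (amap[n] if n in amap
                  else idx[pcs.tip_states[n.taxon.label]])
            P = mk_transition_matrix(alpha, n.edge.length or 0.0, k)
            prob *= P[ps, cs]
        total += prob
        for n in internals:
            margs[n][amap[n]] += prob
    return math.log(total), {n.label: margs[n] / total for n in internals}


class TestTransitionMatrix:
    def test_identity_at_zero_time(self):
        assert np.allclose(mk_transition_matrix(0.7, 0.0), np.eye(4))

    def test_stationary_limit(self):
        P = mk_transition_matrix(1.0, 1e6)
        assert np.allclose(P, 0.25, atol=1e-12)

    @pytest.mark.parametrize("alpha,t,k", [(0.7, 1.3, 4), (2.0, 0.1, 4),
                                           (0.05, 10.0, 3), (1.0, 1.0, 5)])
    def test_matches_matrix_exponential(self, alpha, t, k):
        Q = np.full((k, k), alpha / (k - 1))
        np.fill_diagonal(Q, -alpha)
        assert np.abs(mk_transition_matrix(alpha, t, k) - expm(Q * t)).max() <= 1e-10

    def test_rows_sum_to_one(self):
        P = mk_transition_matrix(0.3, 2.5)
        assert np.allclose(P.sum(axis=1), 1.0)


class TestLikelihood:
    def test_two_tips_zero_branches_identical_states(self):
        tree = get_tree("(A:0.0,B:0.0);")
        pcs = PhyloCharacterSet(tree, {"A": "blue", "B": "blue"}, alpha=1.0)
        assert mk_log_likelihood(pcs) == pytest.approx(math.log(0.25), abs=1e-12)

    def test_two_tips_infinite_branches_independent(self):
        tree = get_tree("(A:1e6,B:1e6);")
        for states in ({"A": "blue", "B": "blue"}, {"A": "blue", "B": "red"}):
            pcs = PhyloCharacterSet(tree, states, alpha=1.0)
            assert mk_log_likelihood(pcs) == pytest.approx(math.log(1 / 16),
                                                           abs=1e-9)

    def test_missing_tip_state_rejected(self):
        tree = get_tree("(A:1.0,B:1.0);")
        with pytest.raises(ValueError):
            PhyloCharacterSet(tree, {"A": "blue"}, alpha=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_pruning_equals_enumeration_random_trees(self, seed):
        """Felsenstein pruning equals brute-force enumeration on random
        Yule trees of up to 6 tips."""
        rng = random.Random(seed)
        n_tips = rng.randint(3, 6)
        tree, tips, _, _ = gen_character_tree(n_tips, 1.0, 0.8, seed=seed)
        alpha = rng.uniform(0.1, 2.0)
        pcs = PhyloCharacterSet(tree, tips, alpha=alpha)
        label_internal_nodes(tree)
        ll_brute, _ = brute_force(pcs, alpha)
        assert mk_log_likelihood(pcs) == pytest.approx(ll_brute, abs=1e-10)


class TestMarginals:
    def test_zero_length_star_all_blue_root_certain(self):
        tree = get_tree("(A:0.0,B:0.0,C:0.0,D:0.0);")
        pcs = PhyloCharacterSet(tree, {t: "blue" for t in "ABCD"}, alpha=1.0)
        probs = marginal_ancestral_probs(pcs)
        root = probs["N0"]
        assert root[DEFAULT_STATES.index("blue")] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration(self, seed):
        tree, tips, _, _ = gen_character_tree(5, 1.0, 0.8, seed=seed + 10)
        pcs = PhyloCharacterSet(tree, tips, alpha=0.8)
        probs = marginal_ancestral_probs(pcs)
        _, brute = brute_force(pcs, 0.8)
        for label, expected in brute.items():
            assert np.abs(probs[label] - expected).max() <= 1e-10

    def test_state_label_permutation_symmetry(self):
        """Permuting state labels permutes the output vectors identically."""
        tree, tips, _, _ = gen_character_tree(6, 1.0, 0.8, seed=4)
        pcs = PhyloCharacterSet(tree, tips, alpha=0.6)
        probs = marginal_ancestral_probs(pcs)
        perm = {"black": "red", "blue": "green", "green": "blue", "red": "black"}
        tips_p = {k: perm[v] for k, v in tips.items()}
        pcs_p = PhyloCharacterSet(tree, tips_p, alpha=0.6)
        probs_p = marginal_ancestral_probs(pcs_p)
        src = [DEFAULT_STATES.index(perm[s]) for s in DEFAULT_STATES]
        for label, vec in probs.items():
            assert np.allclose(probs_p[label][src], vec, atol=1e-12)

    def test_invariant_to_tip_order(self):
        tree1 = get_tree("((A:0.3,B:0.5):0.2,C:0.4);")
        tree2 = get_tree("(C:0.4,(B:0.5,A:0.3):0.2);")
        states = {"A": "blue", "B": "black", "C": "red"}
        p1 = marginal_ancestral_probs(PhyloCharacterSet(tree1, states, alpha=0.5))
        p2 = marginal_ancestral_probs(PhyloCharacterSet(tree2, states, alpha=0.5))
        for tip in states:
            assert np.allclose(p1[tip], p2[tip], atol=1e-12)
        # root vectors agree regardless of child order
        assert np.allclose(p1["N0"], p2["N0"], atol=1e-12)


class TestRateEstimate:
    def test_monomorphic_tips_boundary_flag(self):
        tree = get_tree("((A:1,B:1):1,(C:1,D:1):1);")
        with pytest.warns(UserWarning):
            est = estimate_rate(tree, {t: "blue" for t in "ABCD"})
        assert est.at_boundary
        assert est.alpha == pytest.approx(1e-6)

    def test_recovers_generating_rate_within_factor_two(self):
        tree, tips, _, _ = gen_character_tree(64, 1.0, 0.5, seed=11)
        est = estimate_rate(tree, tips)
        assert 0.25 <= est.alpha <= 1.0

    def test_optimum_beats_perturbations(self):
        tree, tips, _, _ = gen_character_tree(24, 1.0, 0.5, seed=5)
        est = estimate_rate(tree, tips)
        pcs = PhyloCharacterSet(tree, tips, alpha=est.alpha)
        ll_hat = mk_log_likelihood(pcs)
        assert ll_hat >= mk_log_likelihood(pcs, alpha=est.alpha * 0.5) - 1e-9
        assert ll_hat >= mk_log_likelihood(pcs, alpha=est.alpha * 2.0) - 1e-9


class TestTransitions:
    def test_uniform_states_no_transitions(self):
        tree = get_tree("((A:1,B:1)N1:1,(C:1,D:1)N2:1)N0;")
        states = {lbl: "blue" for lbl in ("A", "B", "C", "D", "N0", "N1", "N2")}
        assert count_transitions(tree, states) == {}

    def test_single_planted_change_edge(self):
        tree = get_tree("((A:1,B:1)N1:1,(C:1,D:1)N2:1)N0;")
        states = {"N0": "blue", "N1": "blue", "N2": "black",
                  "A": "blue", "B": "blue", "C": "black", "D": "black"}
        assert count_transitions(tree, states) == {("blue", "black"): 1}

    @pytest.mark.parametrize("seed", range(3))
    def test_counted_changes_bounded_by_true_events(self, seed):
        """Parsimony-style counting from true node states never exceeds the
        number of simulated change events (back-changes collapse)."""
        tree, tips, node_states, events = gen_character_tree(
            32, 1.0, 0.8, seed=seed + 20)
        counted = sum(count_transitions(tree, node_states).values())
        assert counted <= len(events)

    def test_argmax_assignment_is_deterministic(self):
        tree, tips, _, _ = gen_character_tree(12, 1.0, 0.5, seed=7)
        pcs = PhyloCharacterSet(tree, tips, alpha=0.5)
        a1 = assign_max_probability_states(pcs)
        a2 = assign_max_probability_states(pcs)
        assert a1 == a2
        assert set(a1.values()) <= set(DEFAULT_STATES)
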