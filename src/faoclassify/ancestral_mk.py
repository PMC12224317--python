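"""Equal-rates Markov (Mk) ancestral reconstruction of operon categories.

The four operon configurations (black, blue, green, red) are treated as a
discrete character evolving on a rooted phylogeny under the k-state
equal-rates Markov model: every state changes to every other state at the
same rate, so the transition probability over a branch of length t is
closed-form,

    P_ii(t) = 1/k + (k-1)/k * exp(-alpha * k * t / (k-1)),

with all off-diagonal entries equal and alpha the total departure rate per
unit branch length.  Likelihoods use Felsenstein pruning with a uniform
root prior; marginal ancestral state probabilities use the standard
two-pass (inside/outside) algorithm.  Counting edges whose maximum-
probability parent and child states differ gives a lower-bound tally of
independent origins of each configuration.

Trees are dendropy objects; tip states come as a {taxon label: state} map
(the same two-column table the genome scanner writes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DEFAULT_STATES",
    "PhyloCharacterSet",
    "RateEstimate",
    "mk_transition_matrix",
    "mk_log_likelihood",
    "estimate_rate",
    "marginal_ancestral_probs",
    "assign_max_probability_states",
    "count_transitions",
    "label_internal_nodes",
]

DEFAULT_STATES = ("black", "blue", "green", "red")

ALPHA_BOUNDS = (1e-6, 1e3)


@dataclass
class PhyloCharacterSet:
    """A rooted tree with branch lengths, one discrete state per tip, and an
    equal-rates Markov rate ``alpha`` (per unit branch length).  The root
    prior is uniform over the ``states``."""

    tree: dendropy.Tree
    tip_states: dict[str, str]
    alpha: float = 1.0
    states: tuple[str, ...] = DEFAULT_STATES

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError("alpha must be > 0")
        unknown = set(self.tip_states.values()) - set(self.states)
        if unknown:
            raise ValueError(f"tip states not in the state set: {sorted(unknown)}")
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon else leaf.label
            if label not in self.tip_states:
                raise ValueError(f"tip {label!r} has no state")

    @property
    def k(self) -> int:
        return len(self.states)


def mk_transition_matrix(alpha: float, t: float, k: int = 4) -> np.ndarray:
    """Closed-form transition matrix of the equal-rates k-state model."""
    if not (alpha > 0):
        raise ValueError("alpha must be > 0")
    if t < 0:
        raise ValueError("branch length must be >= 0")
    decay = math.exp(-alpha * k * t / (k - 1))
    p_same = 1.0 / k + (k - 1) / k * decay
    p_diff = 1.0 / k - decay / k
    P = np.full((k, k), p_diff)
    np.fill_diagonal(P, p_same)
    return P


def _edge_length(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def _tip_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def _postorder_partials(pcs: PhyloCharacterSet, alpha: float):
    """Pruning up-pass. Returns {node: (partial vector, log scale factor)}."""
    k = pcs.k
    index = {s: i for i, s in enumerate(pcs.states)}
    partials: dict[dendropy.Node, tuple[np.ndarray, float]] = {}
    for node in pcs.tree.postorder_node_iter():
        if node.is_leaf():
            state = pcs.tip_states[_tip_label(node)]
            vec = np.zeros(k)
            vec[index[state]] = 1.0
            partials[node] = (vec, 0.0)
            continue
        vec = np.ones(k)
        logscale = 0.0
        for child in node.child_nodes():
            cvec, cscale = partials[child]
            P = mk_transition_matrix(alpha, _edge_length(child), k)
            vec = vec * (P @ cvec)
            logscale += cscale
        m = vec.max()
        if m <= 0:
            raise FloatingPointError("zero partial likelihood")
        vec = vec / m
        logscale += math.log(m)
        partials[node] = (vec, logscale)
    return partials


def mk_log_likelihood(pcs: PhyloCharacterSet, alpha: float | None = None) -> float:
    """Felsenstein-pruning log-likelihood with a uniform root prior.

    Data that are structurally impossible (conflicting tip states joined by
    zero-length branches) have likelihood zero; -inf is returned.
    """
    alpha = pcs.alpha if alpha is None else alpha
    try:
        partials = _postorder_partials(pcs, alpha)
    except FloatingPointError:
        return -math.inf
    root = pcs.tree.seed_node
    vec, logscale = partials[root]
    prior = 1.0 / pcs.k
    return math.log(float(np.dot(np.full(pcs.k, prior), vec))) + logscale


@dataclass
class RateEstimate:
    alpha: float
    log_likelihood: float
    at_boundary: bool = False
    message: str = ""


def estimate_rate(tree: dendropy.Tree, tip_states: dict[str, str],
                  states: tuple[str, ...] = DEFAULT_STATES) -> RateEstimate:
    """Maximum-likelihood alpha on a log-scale bracketed search.

    With all tips in one state the likelihood is maximized by no change at
    all, so the lower bound is returned with a boundary flag.
    """
    if len(set(tip_states.values())) < 2:
        warnings.warn("all tips share one state; returning the lower rate bound")
        pcs = PhyloCharacterSet(tree, tip_states, alpha=ALPHA_BOUNDS[0], states=states)
        return RateEstimate(ALPHA_BOUNDS[0], mk_log_likelihood(pcs),
                            at_boundary=True, message="monomorphic tips")
    pcs = PhyloCharacterSet(tree, tip_states, alpha=1.0, states=states)

    def nll(log10_alpha: float) -> float:
        return -mk_log_likelihood(pcs, alpha=10.0 ** log10_alpha)

    res = minimize_scalar(nll, bounds=(math.log10(ALPHA_BOUNDS[0]),
                                       math.log10(ALPHA_BOUNDS[1])),
                          method="bounded", options={"xatol": 1e-8})
    alpha_hat = float(10.0 ** res.x)
    boundary = (alpha_hat <= ALPHA_BOUNDS[0] * 1.01
                or alpha_hat >= ALPHA_BOUNDS[1] * 0.99)
    return RateEstimate(alpha_hat, -float(res.fun), at_boundary=boundary)


def marginal_ancestral_probs(pcs: PhyloCharacterSet) -> dict[str, np.ndarray]:
    """Marginal state probabilities for every node (two-pass algorithm).

    Returns {node label: probability vector over ``pcs.states``}; internal
    nodes are labelled first via :func:`label_internal_nodes` if unlabeled.
    Each vector is normalized to sum to 1.
    """
    label_internal_nodes(pcs.tree)
    k = pcs.k
    alpha = pcs.alpha
    partials = _postorder_partials(pcs, alpha)
    prior = np.full(k, 1.0 / k)

    outside: dict[dendropy.Node, np.ndarray] = {pcs.tree.seed_node: prior.copy()}
    result: dict[str, np.ndarray] = {}
    for node in pcs.tree.preorder_node_iter():
        if node is not pcs.tree.seed_node:
            parent = node.parent_node
            # message from the rest of the tree into `node`'s edge
            up_parent = outside[parent].copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                svec, _ = partials[sib]
                P = mk_transition_matrix(alpha, _edge_length(sib), k)
                up_parent = up_parent * (P @ svec)
            P = mk_transition_matrix(alpha, _edge_length(node), k)
            out = P.T @ up_parent
            m = out.max()
            outside[node] = out / m if m > 0 else out
        vec, _ = partials[node]
        marg = vec * outside[node]
        total = marg.sum()
        if total <= 0:
            raise FloatingPointError("zero marginal probability")
        result[_node_key(node)] = marg / total
    return result


def _node_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return _tip_label(node)
    return node.label


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> None:
    """Assign deterministic preorder labels N0, N1, ... to unlabeled
    internal nodes (idempotent)."""
    i = 0
    for node in tree.preorder_internal_node_iter():
        if not node.label:
            node.label = f"{prefix}{i}"
        i += 1


def assign_max_probability_states(
    pcs: PhyloCharacterSet, probs: dict[str, np.ndarray] | None = None
) -> dict[str, str]:
    """Argmax state per node; ties break toward the parent's assigned state,
    then lexicographically, so the output is deterministic."""
    if probs is None:
        probs = marginal_ancestral_probs(pcs)
    states = pcs.states
    assignment: dict[str, str] = {}
    for node in pcs.tree.preorder_node_iter():
        key = _node_key(node)
        p = probs[key]
        best = p.max()
        candidates = sorted(states[i] for i in np.flatnonzero(p >= best - 1e-12))
        if len(candidates) > 1 and node.parent_node is not None:
            parent_state = assignment[_node_key(node.parent_node)]
            if parent_state in candidates:
                assignment[key] = parent_state
                continue
        assignment[key] = candidates[0]
    return assignment


def count_transitions(tree: dendropy.Tree,
                      node_states: dict[str, str]) -> dict[tuple[str, str], int]:
    """Count edges whose parent and child states differ, keyed by the
    ordered (parent_state, child_state) pair."""
    counts: dict[tuple[str, str], int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        ps = node_states[_node_key(node.parent_node)]
        cs = node_states[_node_key(node)]
        if ps != cs:
            counts[(ps, cs)] = counts.get((ps, cs), 0) + 1
    return counts
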