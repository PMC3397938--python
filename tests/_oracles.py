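"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's pruning/up-down code paths: the
likelihood oracle sums over all interior-node state assignments, the
marginal oracle is the same enumeration restricted to one node, the MRCA
oracle intersects root-to-tip paths, and the transition-probability oracle
integrates the forward Kolmogorov equation numerically.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.integrate import solve_ivp

from mkasr.mk_likelihood import RateParameters, transition_matrix
from mkasr.trees import Tree, TreeNode


def random_binary_tree(n_tips: int, rng, max_blen: float = 1.5) -> Tree:
    """Random topology by sequential pair joining; uniform branch lengths."""
    nodes = [
        TreeNode(label=f"t{i}", length=float(rng.uniform(0.01, max_blen)))
        for i in range(n_tips)
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[int(i)], nodes[int(j)]
        p = TreeNode(length=float(rng.uniform(0.01, max_blen)))
        p.add_child(a)
        p.add_child(b)
        nodes = [x for x in nodes if x is not a and x is not b] + [p]
    root = TreeNode()
    for x in nodes:
        root.add_child(x)
    return Tree(root)


def random_partials(tree: Tree, k: int, rng, p_missing: float = 0.15) -> dict:
    partials = {}
    for tip in tree.tips():
        if rng.random() < p_missing:
            partials[tip.label] = np.ones(k)
        else:
            v = np.zeros(k)
            v[int(rng.integers(k))] = 1.0
            partials[tip.label] = v
    return partials


def _joint_probability(tree, rates, kappa, partials, pi, amap):
    prob = pi[amap[id(tree.root)]]
    for node in tree.postorder():
        if node is tree.root:
            continue
        ps = amap[id(node.parent)]
        P = transition_matrix(rates, float(node.length) ** kappa)
        if node.is_tip:
            prob *= float(P[ps] @ partials[node.label])
        else:
            prob *= P[ps, amap[id(node)]]
    return prob


def enum_loglik(tree: Tree, rates: RateParameters, kappa: float, partials, pi) -> float:
    """Likelihood by exhaustive summation over interior-node states."""
    internals = [n for n in tree.postorder() if not n.is_tip]
    k = rates.k
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        total += _joint_probability(tree, rates, kappa, partials, pi, amap)
    return math.log(total)


def enum_marginal(tree: Tree, rates: RateParameters, kappa: float, partials, pi, node):
    """P(node = s | tips) by the same enumeration, Bayes-normalized."""
    internals = [n for n in tree.postorder() if not n.is_tip]
    k = rates.k
    out = np.zeros(k)
    if node.is_tip:
        # condition on the tip's own partial as well
        for assign in itertools.product(range(k), repeat=len(internals)):
            amap = {id(n): s for n, s in zip(internals, assign)}
            base = pi[amap[id(tree.root)]]
            for nd in tree.postorder():
                if nd is tree.root:
                    continue
                ps = amap[id(nd.parent)]
                P = transition_matrix(rates, float(nd.length) ** kappa)
                if nd is node:
                    continue
                if nd.is_tip:
                    base *= float(P[ps] @ partials[nd.label])
                else:
                    base *= P[ps, amap[id(nd)]]
            Pn = transition_matrix(rates, float(node.length) ** kappa)
            ps = amap[id(node.parent)]
            for s in range(k):
                out[s] += base * Pn[ps, s] * partials[node.label][s]
        return out / out.sum()
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {id(n): s for n, s in zip(internals, assign)}
        out[amap[id(node)]] += _joint_probability(tree, rates, kappa, partials, pi, amap)
    return out / out.sum()


def mrca_by_paths(tree: Tree, taxon_set) -> TreeNode:
    """MRCA by intersecting root-to-tip paths (O(n^2))."""
    tm = tree.tip_map()
    paths = []
    for taxon in taxon_set:
        path = []
        node = tm[taxon]
        while node is not None:
            path.append(node)
            node = node.parent
        paths.append(path[::-1])  # root first
    deepest = None
    for level in range(min(len(p) for p in paths)):
        first = paths[0][level]
        if all(p[level] is first for p in paths):
            deepest = first
        else:
            break
    return deepest


def transition_by_ode(rates: RateParameters, t: float, rtol: float = 1e-12) -> np.ndarray:
    """Solve dP/dt = P Q row by row with an adaptive integrator."""
    k = rates.k
    Q = rates.generator()
    if t == 0:
        return np.eye(k)
    out = np.empty((k, k))
    for i in range(k):
        sol = solve_ivp(
            lambda _, p: p @ Q,
            (0.0, t),
            np.eye(k)[i],
            rtol=rtol,
            atol=1e-14,
            method="DOP853",
        )
        out[i] = sol.y[:, -1]
    return out
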