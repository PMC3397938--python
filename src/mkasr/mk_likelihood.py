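"""Mk-model likelihood on a κ-transformed tree.

The character evolves along each branch as a continuous-time Markov chain
with instantaneous rate matrix Q (off-diagonal rates q_ij >= 0, rows summing
to zero).  Branch lengths are first raised to the power κ.  The likelihood
is computed by the pruning algorithm (post-order propagation of per-state
conditional likelihoods) with per-node rescaling accumulated in log space to
guard against underflow on large trees.  Marginal ancestral-state
probabilities at a node come from combining the below-node conditional
likelihoods with an "outside" pass over the rest of the tree.

For binary characters the transition probabilities have the closed form

    P00(t) = (q10 + q01 e^{-(q01+q10) t}) / (q01 + q10)

which the fast path uses; k >= 3 goes through a scaled-and-squared matrix
exponential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .trees import Tree, TreeNode, TreeError

__all__ = [
    "RateParameters",
    "RootPrior",
    "LikelihoodError",
    "transition_matrix",
    "mk_loglik",
    "marginal_node_probs",
    "PruningEngine",
]


class LikelihoodError(ValueError):
    """Raised for invalid rate parameters or numerical failure."""


@dataclass(frozen=True)
class RateParameters:
    """Off-diagonal rates of a k-state Mk generator.

    ``rates`` lists q_ij row by row, skipping the diagonal: for k=2 it is
    (q01, q10); for k=3 it is (q01, q02, q10, q12, q20, q21).
    """

    k: int
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = self.k * (self.k - 1)
        if len(self.rates) != expected:
            raise LikelihoodError(
                f"need {expected} off-diagonal rates for k={self.k}, "
                f"got {len(self.rates)}"
            )
        if any(r < 0 for r in self.rates):
            raise LikelihoodError("rates must be >= 0")
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))

    @classmethod
    def binary(cls, q01: float, q10: float) -> "RateParameters":
        return cls(k=2, rates=(q01, q10))

    @property
    def q01(self) -> float:
        if self.k != 2:
            raise LikelihoodError("q01 is defined for binary characters only")
        return self.rates[0]

    @property
    def q10(self) -> float:
        if self.k != 2:
            raise LikelihoodError("q10 is defined for binary characters only")
        return self.rates[1]

    def generator(self) -> np.ndarray:
        """The k×k rate matrix Q with rows summing to zero."""
        Q = np.zeros((self.k, self.k))
        it = iter(self.rates)
        for i in range(self.k):
            for j in range(self.k):
                if i != j:
                    Q[i, j] = next(it)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of Q (left null vector, normalized)."""
        Q = self.generator()
        A = np.vstack([Q.T, np.ones(self.k)])
        b = np.zeros(self.k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass(frozen=True)
class RootPrior:
    """Prior over the state at the root.

    The default is uniform; the stationary distribution of the rate matrix
    is the standard alternative.  The choice is carried as metadata in all
    results.
    """

    probabilities: tuple[float, ...]
    label: str = "custom"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise LikelihoodError("root prior must be a probability vector")
        object.__setattr__(self, "probabilities", tuple(float(x) for x in p))

    @classmethod
    def uniform(cls, k: int) -> "RootPrior":
        return cls(tuple([1.0 / k] * k), label="uniform")

    @classmethod
    def stationary(cls, rates: RateParameters) -> "RootPrior":
        return cls(tuple(rates.stationary_distribution()), label="stationary")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.probabilities)


def transition_matrix(rates: RateParameters, t: float) -> np.ndarray:
    """P(t) = exp(Qt): state-to-state transition probabilities over a branch
    of (transformed) length t.  Closed form for k=2, matrix exponential for
    k >= 3.  An all-zero generator yields the identity (with a warning for
    t > 0, where the character cannot change at all)."""
    if not (t >= 0 and math.isfinite(t)):
        raise LikelihoodError(f"branch length must be finite and >= 0, got {t}")
    k = rates.k
    if all(r == 0 for r in rates.rates):
        if t > 0:
            warnings.warn("all-zero generator: transition matrix is the identity")
        return np.eye(k)
    if t == 0:
        return np.eye(k)
    if k == 2:
        q01, q10 = rates.rates
        s = q01 + q10
        e = math.exp(-s * t)
        p00 = (q10 + q01 * e) / s
        p11 = (q01 + q10 * e) / s
        return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])
    P = expm(rates.generator() * t)
    # clip tiny negative round-off and renormalize rows
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


class PruningEngine:
    """Pruning-algorithm likelihood for one (tree, tip-partials) pair.

    Flattens the tree once into post-order index arrays so that repeated
    likelihood evaluations (as in MCMC) touch no Python object graph.  The
    binary-character path is scalar arithmetic over flat lists; the general
    path uses an eigendecomposition of Q (matrix-exponential fallback) to
    get all branch transition matrices at once.
    """

    def __init__(self, tree: Tree, partials: Mapping[str, np.ndarray], k: int):
        self.tree = tree
        self.k = k
        nodes = list(tree.postorder())  # children precede parents; root last
        self._nodes = nodes
        self._index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.root_index = self.n_nodes - 1

        parent = np.full(self.n_nodes, -1, dtype=np.int64)
        blen = np.zeros(self.n_nodes)
        is_tip = np.zeros(self.n_nodes, dtype=bool)
        tip_partials = np.ones((self.n_nodes, k))
        for i, node in enumerate(nodes):
            if node.parent is not None:
                parent[i] = self._index[id(node.parent)]
                blen[i] = node.length
            if node.is_tip:
                is_tip[i] = True
                try:
                    vec = np.asarray(partials[node.label], dtype=float)
                except KeyError:
                    raise LikelihoodError(
                        f"no tip partial for taxon {node.label!r}"
                    ) from None
                if vec.shape != (k,) or not vec.any():
                    raise LikelihoodError(
                        f"tip partial for {node.label!r} must be a non-zero "
                        f"vector of length {k}"
                    )
                tip_partials[i] = vec
        self.parent = parent
        self.blen = blen
        self.is_tip = is_tip
        self.tip_partials = tip_partials
        # edges processed in post-order of the child node (root excluded)
        self.edge_order = [i for i in range(self.n_nodes) if parent[i] >= 0]
        # flat copies for the scalar binary fast path
        self._parent_l = parent.tolist()
        self._istip_l = is_tip.tolist()
        self._tp0 = tip_partials[:, 0].tolist()
        self._tp1 = tip_partials[:, 1].tolist() if k >= 2 else None

    # -- transition matrices on all edges ----------------------------------

    def _edge_lengths(self, kappa: float) -> np.ndarray:
        if kappa == 1.0:
            return self.blen
        # 0**0 == 1 by convention (numpy agrees)
        return self.blen ** kappa

    def _edge_matrices(self, rates: RateParameters, kappa: float) -> np.ndarray:
        """(n_nodes, k, k) transition matrix per edge (identity at the root
        slot, unused)."""
        t = self._edge_lengths(kappa)
        Q = rates.generator()
        if not np.any(Q):
            return np.broadcast_to(np.eye(self.k), (self.n_nodes, self.k, self.k)).copy()
        try:
            lam, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            E = np.exp(np.outer(t, lam))  # (n, k)
            P = np.einsum("ij,nj,jk->nik", V, E, Vinv)
            P = np.real_if_close(P, tol=1e6)
            if np.iscomplexobj(P) or not np.all(np.isfinite(P)):
                raise np.linalg.LinAlgError
            # validate against one exact exponential
            probe = int(np.argmax(t))
            if np.max(np.abs(P[probe] - expm(Q * t[probe]))) > 1e-9:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            P = np.stack([expm(Q * ti) for ti in t])
        P = np.clip(P.astype(float), 0.0, None)
        return P / P.sum(axis=2, keepdims=True)

    # -- likelihood ---------------------------------------------------------

    def loglik_binary(
        self,
        q01: float,
        q10: float,
        kappa: float,
        pi0: float = 0.5,
        pi1: float = 0.5,
    ) -> float:
        """Fast scalar pruning pass for k=2."""
        s = q01 + q10
        if s <= 0.0:
            # no change possible anywhere; likelihood of compatible data is
            # the root prior mass on globally compatible states
            return self.loglik(
                RateParameters.binary(q01, q10),
                kappa,
                RootPrior((pi0, pi1)),
            )
        t = self._edge_lengths(kappa)
        e = np.exp(-s * t)
        p00 = (q10 + q01 * e) / s
        p11 = (q01 + q10 * e) / s
        p00l = p00.tolist()
        p11l = p11.tolist()
        L0 = list(self._tp0)
        L1 = list(self._tp1)
        parent = self._parent_l
        istip = self._istip_l
        logscale = 0.0
        for i in self.edge_order:
            a = L0[i]
            b = L1[i]
            if not istip[i]:
                sc = a + b
                if sc <= 0.0:
                    return -math.inf
                a /= sc
                b /= sc
                logscale += math.log(sc)
            P00 = p00l[i]
            P11 = p11l[i]
            m0 = P00 * a + (1.0 - P00) * b
            m1 = (1.0 - P11) * a + P11 * b
            p = parent[i]
            L0[p] *= m0
            L1[p] *= m1
        r = self.root_index
        lik = pi0 * L0[r] + pi1 * L1[r]
        if lik <= 0.0:
            return -math.inf
        return math.log(lik) + logscale

    def loglik(
        self,
        rates: RateParameters,
        kappa: float,
        root_prior: RootPrior | None = None,
    ) -> float:
        """General-k pruning pass (uniform root prior unless given)."""
        pi = (root_prior or RootPrior.uniform(self.k)).as_array()
        P = self._edge_matrices(rates, kappa)
        L = self.tip_partials.copy()
        logscale = 0.0
        for i in self.edge_order:
            v = L[i]
            if not self.is_tip[i]:
                sc = v.sum()
                if sc <= 0.0:
                    return -math.inf
                v = v / sc
                logscale += math.log(sc)
            L[self.parent[i]] *= P[i] @ v
        lik = float(pi @ L[self.root_index])
        if not math.isfinite(lik) or lik <= 0.0:
            return -math.inf
        return math.log(lik) + logscale

    # -- marginal reconstruction -------------------------------------------

    def node_marginals(
        self,
        rates: RateParameters,
        kappa: float,
        root_prior: RootPrior | None = None,
    ) -> np.ndarray:
        """Marginal state probabilities at every node, shape (n_nodes, k).

        Down pass: L[v][s] = P(tips below v | state s at v).  Outside pass:
        O[v][s] = contribution of everything outside v's subtree (O at the
        root is the root prior).  The marginal at v is the normalized
        product L[v]*O[v]; each row sums to 1.
        """
        pi = (root_prior or RootPrior.uniform(self.k)).as_array()
        P = self._edge_matrices(rates, kappa)

        # down pass with per-node normalization (scaling cancels at the end)
        L = self.tip_partials.copy()
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.edge_order:
            children[self.parent[i]].append(i)
        for i in self.edge_order:
            if not self.is_tip[i]:
                sc = L[i].sum()
                if sc <= 0.0:
                    raise LikelihoodError(f"zero conditional likelihood at node {i}")
                L[i] = L[i] / sc
            L[self.parent[i]] *= P[i] @ L[i]
        r = self.root_index
        sc = L[r].sum()
        if sc <= 0.0:
            raise LikelihoodError("zero likelihood at the root")
        L[r] = L[r] / sc

        # messages up through each edge: M[i][s_parent] = sum_s P[i][s_parent,s] L[i][s]
        M = np.empty((self.n_nodes, self.k))
        for i in self.edge_order:
            M[i] = P[i] @ L[i]

        O = np.empty((self.n_nodes, self.k))
        O[r] = pi / pi.sum()
        for i in reversed(self.edge_order):  # parents before children
            p = self.parent[i]
            out = O[p].copy()
            for sib in children[p]:
                if sib != i:
                    out *= M[sib]
            O[i] = out @ P[i]  # O_i[s] = sum_t out[t] P[i][t, s]
            tot = O[i].sum()
            if tot > 0:
                O[i] /= tot

        marg = L * O
        tot = marg.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise LikelihoodError("degenerate marginal (zero total probability)")
        return marg / tot

    def node_index(self, node: TreeNode) -> int:
        try:
            return self._index[id(node)]
        except KeyError:
            raise LikelihoodError("node does not belong to this tree") from None


def mk_loglik(
    tree: Tree,
    rates: RateParameters,
    kappa: float,
    partials: Mapping[str, np.ndarray],
    root_prior: RootPrior | None = None,
) -> float:
    """Log-likelihood of one character on a κ-transformed tree."""
    engine = PruningEngine(tree, partials, rates.k)
    ll = engine.loglik(rates, kappa, root_prior)
    if not math.isfinite(ll) and ll != -math.inf:
        raise LikelihoodError("non-finite log-likelihood")
    return ll


def marginal_node_probs(
    tree: Tree,
    rates: RateParameters,
    kappa: float,
    partials: Mapping[str, np.ndarray],
    root_prior: RootPrior | None = None,
    node: TreeNode | None = None,
) -> np.ndarray:
    """Marginal posterior state probabilities at ``node`` (default: root)."""
    engine = PruningEngine(tree, partials, rates.k)
    marg = engine.node_marginals(rates, kappa, root_prior)
    idx = engine.root_index if node is None else engine.node_index(node)
    return marg[idx]
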