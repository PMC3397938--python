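"""Synthetic tree samples and characters for end-to-end testing.

A Bayesian posterior tree sample is emulated by a focal Yule (pure-birth)
topology whose branch lengths are multiplied by independent lognormal jitter
per tree, optionally with random NNI rearrangements for topological
variation.  Characters are simulated forward along the κ-transformed focal
tree under known rates, so recovery of the truth can be tested at every
stage.  Named fixtures bundle trees, characters, node queries and the truth
record; the "morindeae-like" fixture mirrors the shape of the study system
(61 ingroup tips in four clades plus two outgroup taxa, seven MRCA-defined
query nodes A–G).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .characters import MISSING, CharacterColumn, write_character_matrix
from .mk_likelihood import RateParameters, transition_matrix
from .trees import (
    NodeQuery,
    Tree,
    TreeNode,
    TreeSample,
    mrca,
    write_tree_sample,
)

__all__ = [
    "SimScenario",
    "FixtureBundle",
    "simulate_yule_tree",
    "simulate_tree_sample",
    "simulate_character",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass
class SimScenario:
    """Study-shaped simulation conditions.

    Defaults follow the scale of the target analysis: ~60 tips, a moderate
    posterior sample, lognormal branch-length jitter with sd 0.1 (mild
    posterior uncertainty), Yule birth rate 1 (tree height ~ log n).
    """

    n_taxa: int = 61
    n_trees: int = 100
    birth_rate: float = 1.0
    jitter_sd: float = 0.1
    nni_fraction: float = 0.0
    rates: RateParameters = field(default_factory=lambda: RateParameters.binary(1.0, 0.2))
    kappa: float = 1.0
    root_dist: tuple[float, ...] = (1.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if self.jitter_sd < 0:
            raise ValueError("jitter sd must be >= 0")
        if any(r < 0 for r in self.rates.rates) or not any(self.rates.rates):
            raise ValueError("rates must be >= 0 with at least one positive")


def simulate_yule_tree(
    n_taxa: int,
    birth_rate: float,
    rng: np.random.Generator,
    labels: list[str] | None = None,
) -> Tree:
    """Pure-birth tree: lineages split at rate ``birth_rate`` each until
    ``n_taxa`` tips exist; a final waiting time extends the terminal
    branches so none end at zero length."""
    root = TreeNode()
    active = [root.add_child(TreeNode(length=0.0)), root.add_child(TreeNode(length=0.0))]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += wait
        idx = rng.integers(len(active))
        split = active.pop(int(idx))
        active.append(split.add_child(TreeNode(length=0.0)))
        active.append(split.add_child(TreeNode(length=0.0)))
    final = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += final
    if labels is None:
        labels = [f"t{i + 1:03d}" for i in range(n_taxa)]
    order = rng.permutation(n_taxa)
    for node, j in zip(active, order):
        node.label = labels[int(j)]
    return Tree(root)


def _jitter(tree: Tree, sd: float, rng: np.random.Generator) -> Tree:
    out = tree.copy()
    if sd > 0:
        for node in out.postorder():
            if node is not out.root:
                node.length *= float(rng.lognormal(0.0, sd))
    return out


def _nni(tree: Tree, rng: np.random.Generator) -> None:
    """One random nearest-neighbour interchange, in place."""
    internal_edges = [
        n
        for n in tree.postorder()
        if not n.is_tip and n.parent is not None and n.parent.parent is not None
    ]
    if not internal_edges:
        return
    v = internal_edges[int(rng.integers(len(internal_edges)))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    if not siblings or not v.children:
        return
    s = siblings[int(rng.integers(len(siblings)))]
    c = v.children[int(rng.integers(len(v.children)))]
    u.children[u.children.index(s)] = c
    v.children[v.children.index(c)] = s
    s.parent, c.parent = v, u
    s.length, c.length = c.length, s.length


def simulate_tree_sample(scenario: SimScenario, rng: np.random.Generator | None = None) -> TreeSample:
    """A posterior-like sample: focal Yule topology, per-tree lognormal
    branch jitter, optional NNI topological perturbation."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    focal = simulate_yule_tree(scenario.n_taxa, scenario.birth_rate, rng)
    trees = []
    for _ in range(scenario.n_trees):
        t = _jitter(focal, scenario.jitter_sd, rng)
        if scenario.nni_fraction > 0:
            n_moves = rng.binomial(max(scenario.n_taxa - 2, 1), scenario.nni_fraction)
            for _ in range(int(n_moves)):
                _nni(t, rng)
        trees.append(t)
    return TreeSample(trees, provenance=f"yule simulation (seed {scenario.seed})")


def simulate_character(
    tree: Tree,
    rates: RateParameters,
    kappa: float,
    root_dist,
    rng: np.random.Generator,
    name: str = "sim",
) -> CharacterColumn:
    """Evolve one discrete character down the κ-transformed tree.

    The root state is drawn from ``root_dist``; each branch applies the
    transition matrix of its transformed length.
    """
    k = rates.k
    pi = np.asarray(root_dist, dtype=float)
    pi = pi / pi.sum()
    states: dict[int, int] = {}
    assignments: dict[str, int] = {}
    root_state = int(rng.choice(k, p=pi))
    # cache transition rows per transformed length (jittered trees repeat few)
    cache: dict[float, np.ndarray] = {}
    order = list(tree.preorder())
    states[id(tree.root)] = root_state
    for node in order:
        if node is tree.root:
            continue
        t = float(node.length) ** kappa
        P = cache.get(t)
        if P is None:
            P = transition_matrix(rates, t)
            cache[t] = P
        parent_state = states[id(node.parent)]
        states[id(node)] = int(rng.choice(k, p=P[parent_state]))
        if node.is_tip:
            assignments[node.label] = states[id(node)]
    return CharacterColumn(
        name=name, state_space=tuple(range(k)), assignments=assignments
    )


# ---------------------------------------------------------------------------
# named fixtures

FIXTURE_NAMES = ("symmetric", "asymmetric-ratio5", "morindeae-like", "prior-only")


@dataclass
class FixtureBundle:
    """Trees + characters + node queries + the simulation truth."""

    name: str
    tree_sample: TreeSample
    columns: list[CharacterColumn]
    queries: list[NodeQuery]
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        """Write the bundle in the engine's own input formats (Newick list,
        CSV character matrix, YAML query file, YAML truth record)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trees": outdir / "trees.nwk",
            "characters": outdir / "characters.csv",
            "queries": outdir / "queries.yaml",
            "truth": outdir / "truth.yaml",
        }
        write_tree_sample(self.tree_sample, paths["trees"])
        write_character_matrix(self.columns, paths["characters"])
        with open(paths["queries"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {q.name: sorted(q.taxon_set) for q in self.queries}, fh
            )
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.truth, fh)
        return paths


def _clade_tree(
    clades: dict[str, int],
    stem_length: float,
    rng: np.random.Generator,
    birth_rate: float = 1.0,
) -> Tree:
    """A ladder of named clades: (A,(B,(C,D))) backbone, each clade a Yule
    subtree whose tips are labelled '<CLADE>_<i>'."""
    subtrees = {}
    for cname, size in clades.items():
        labels = [f"{cname}_{i + 1:02d}" for i in range(size)]
        if size == 1:
            node = TreeNode(label=labels[0], length=stem_length)
        else:
            sub = simulate_yule_tree(size, birth_rate, rng, labels=labels)
            node = sub.root
            node.length = stem_length
        subtrees[cname] = node

    names = list(clades)
    root = TreeNode()
    current = root
    for cname in names[:-2]:
        current.add_child(subtrees[cname])
        nxt = TreeNode(length=stem_length)
        current.add_child(nxt)
        current = nxt
    current.add_child(subtrees[names[-2]])
    current.add_child(subtrees[names[-1]])
    return Tree(root)


def make_fixture(name: str, seed: int = 20120716) -> FixtureBundle:
    """Reproducible named test bundles.

    - "symmetric": equal forward/backward rates, truth ratio 1.
    - "asymmetric-ratio5": 60 tips, q01/q10 = 5 (q01=1.0, q10=0.2), κ=1.
    - "morindeae-like": 61 ingroup tips in four clades (APP, MOR, COE, GYN)
      plus two outgroup taxa; four clade-biased binary characters simulated
      under known rates; seven MRCA queries A–G.
    - "prior-only": every character state missing, so the posterior equals
      the prior.
    """
    rng = np.random.default_rng(seed)
    if name == "symmetric":
        rates = RateParameters.binary(0.3, 0.3)
        scenario = SimScenario(
            n_taxa=20, n_trees=25, jitter_sd=0.1, rates=rates, kappa=1.0,
            root_dist=(0.5, 0.5), seed=seed,
        )
        sample = simulate_tree_sample(scenario, rng)
        columns = [
            simulate_character(sample[0], rates, 1.0, (0.5, 0.5), rng, name=f"sym{i + 1}")
            for i in range(3)
        ]
        queries = [NodeQuery("root", frozenset(sample.taxon_set))]
        truth = {"q01": 0.3, "q10": 0.3, "ratio": 1.0, "kappa": 1.0}
    elif name == "asymmetric-ratio5":
        rates = RateParameters.binary(1.0, 0.2)
        scenario = SimScenario(
            n_taxa=60, n_trees=25, jitter_sd=0.1, rates=rates, kappa=1.0,
            root_dist=(1.0, 0.0), seed=seed,
        )
        sample = simulate_tree_sample(scenario, rng)
        columns = [
            simulate_character(sample[0], rates, 1.0, (1.0, 0.0), rng, name="asym")
        ]
        queries = [NodeQuery("root", frozenset(sample.taxon_set))]
        truth = {"q01": 0.5, "q10": 0.1, "ratio": 5.0, "kappa": 1.0}
    elif name == "morindeae-like":
        return _morindeae_like(seed, rng)
    elif name == "prior-only":
        scenario = SimScenario(
            n_taxa=12, n_trees=5, jitter_sd=0.05,
            rates=RateParameters.binary(0.3, 0.3), kappa=1.0,
            root_dist=(0.5, 0.5), seed=seed,
        )
        sample = simulate_tree_sample(scenario, rng)
        taxa = sorted(sample.taxon_set)
        columns = [
            CharacterColumn(
                name="blank",
                state_space=(0, 1),
                assignments={t: MISSING for t in taxa},
            )
        ]
        queries = [NodeQuery("root", frozenset(taxa))]
        truth = {
            "kappa_prior_mean": 2.5,
            "m_prior_mean": 5.0,
            "model_prior": [0.25, 0.25, 0.25, 0.25],
        }
    else:
        raise ValueError(
            f"unknown fixture {name!r}; choose one of {', '.join(FIXTURE_NAMES)}"
        )
    return FixtureBundle(name, sample, columns, queries, truth)


def _morindeae_like(seed: int, rng: np.random.Generator) -> FixtureBundle:
    clades = {"APP": 6, "MOR": 12, "COE": 8, "GYN": 35}
    ingroup = _clade_tree(clades, stem_length=0.25, rng=rng)
    # attach two outgroup taxa below the ingroup root
    root = TreeNode()
    og = TreeNode(length=0.3)
    og.add_child(TreeNode(label="OUT_1", length=0.2))
    og.add_child(TreeNode(label="OUT_2", length=0.2))
    root.add_child(og)
    in_root = ingroup.root
    in_root.length = 0.3
    root.add_child(in_root)
    focal = Tree(root)

    scenario_like = SimScenario(n_taxa=63, n_trees=50, jitter_sd=0.1, seed=seed)
    trees = [_jitter(focal, scenario_like.jitter_sd, rng) for _ in range(scenario_like.n_trees)]
    sample = TreeSample(trees, provenance=f"morindeae-like fixture (seed {seed})")

    # four clade-biased binary characters simulated under known rates; the
    # growth-form analogue gets a third (herbaceous-like) state confined to
    # one outgroup taxon, mirroring the study's coding
    char_specs = {
        "growth_form": (RateParameters.binary(1.0, 0.2), (1.0, 0.0)),
        "inflorescence": (RateParameters.binary(0.6, 0.9), (1.0, 0.0)),
        "flower_size": (RateParameters.binary(0.8, 0.3), (1.0, 0.0)),
        "fruit_type": (RateParameters.binary(0.6, 0.9), (0.0, 1.0)),
    }
    columns = []
    truth_rates = {}
    for cname, (rates, root_dist) in char_specs.items():
        col = simulate_character(focal, rates, 1.0, root_dist, rng, name=cname)
        if cname == "growth_form":
            asg = dict(col.assignments)
            asg["OUT_2"] = 2  # herbaceous analogue, outgroup only
            col = CharacterColumn(cname, (0, 1, 2), asg)
        columns.append(col)
        truth_rates[cname] = {
            "q01": rates.q01,
            "q10": rates.q10,
            "ratio": rates.q01 / rates.q10,
        }

    tipsets = {c: frozenset(f"{c}_{i + 1:02d}" for i in range(n)) for c, n in clades.items()}
    ingroup_taxa = frozenset().union(*tipsets.values())
    queries = [
        NodeQuery("A", ingroup_taxa),
        NodeQuery("B", tipsets["MOR"] | tipsets["COE"] | tipsets["GYN"]),
        NodeQuery("C", tipsets["COE"] | tipsets["GYN"]),
        NodeQuery("D", tipsets["APP"]),
        NodeQuery("E", tipsets["MOR"]),
        NodeQuery("F", tipsets["COE"]),
        NodeQuery("G", tipsets["GYN"]),
    ]
    for q in queries:  # every query must resolve on every tree
        for tree in sample:
            mrca(tree, q.taxon_set)
    truth = {
        "kappa": 1.0,
        "rates": truth_rates,
        "outgroup": ["OUT_1", "OUT_2"],
        "n_ingroup": 61,
    }
    return FixtureBundle("morindeae-like", sample, columns, queries, truth)
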