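"""Rooted trees and posterior tree samples.

Trees here are plain rooted trees with taxon-labelled tips and non-negative
branch lengths in expected substitutions per site.  Polytomies are legal and
consumers must not assume bifurcation.  Parsing of Newick and NEXUS (with an
optional translate table) is delegated to dendropy; the in-memory
representation is a lightweight node structure convenient for the pruning
likelihood.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Tree",
    "TreeNode",
    "TreeSample",
    "NodeQuery",
    "TreeError",
    "parse_newick",
    "read_tree_sample",
    "write_tree_sample",
    "prune_taxa",
    "mrca",
    "kappa_transform",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


class TreeNode:
    """A node in a rooted tree.

    Tips carry a taxon ``label``; internal nodes have ``label`` None.
    ``length`` is the length of the branch subtending the node (None at the
    root).
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<TreeNode {kind} label={self.label!r} length={self.length}>"


class Tree:
    """A rooted tree over a set of uniquely labelled tips."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- basic traversal ---------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tips())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    @property
    def is_degenerate(self) -> bool:
        """True for a single-tip tree (accepted but useless for inference)."""
        return self.root.is_tip

    # -- construction / validation ----------------------------------------

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.postorder():
            if node.is_tip:
                if node.label is None:
                    raise TreeError("tip without a taxon label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)
            if node is not self.root:
                if node.length is None:
                    raise TreeError(
                        f"missing branch length on node {node.label or '<internal>'}"
                    )
                if node.length < 0:
                    raise TreeError(
                        f"negative branch length {node.length} on node "
                        f"{node.label or '<internal>'}"
                    )

    def copy(self) -> "Tree":
        def _copy(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add_child(_copy(child))
            return new

        return Tree(_copy(self.root))

    # -- queries -----------------------------------------------------------

    def tip_map(self) -> dict[str, TreeNode]:
        return {t.label: t for t in self.tips()}

    def distance(self, a: str, b: str) -> float:
        """Patristic distance between two tips (sum of branch lengths)."""
        tm = self.tip_map()
        for t in (a, b):
            if t not in tm:
                raise TreeError(f"unknown taxon {t!r}")
        anc = mrca(self, {a, b}) if a != b else tm[a]
        dist = 0.0
        for t in (a, b):
            node = tm[t]
            while node is not anc:
                dist += node.length
                node = node.parent
        return dist

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def _quote(label: str) -> str:
            if re.search(r"[\s()\[\]{}:;,'\"]", label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def _fmt(node: TreeNode) -> str:
            if node.is_tip:
                s = _quote(node.label)
            else:
                s = "(" + ",".join(_fmt(c) for c in node.children) + ")"
            if node.length is not None:
                s += f":{node.length:.12g}"
            return s

        return _fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree with {self.n_tips} tips>"


@dataclass
class TreeSample:
    """An ordered posterior sample of trees over one shared taxon set."""

    trees: list[Tree]
    provenance: str = ""
    taxon_set: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("tree sample is empty")
        reference = self.trees[0].taxa
        for i, tree in enumerate(self.trees[1:], start=1):
            if tree.taxa != reference:
                diff = sorted(tree.taxa.symmetric_difference(reference))
                raise TreeError(
                    f"tree {i} has a different taxon set; symmetric "
                    f"difference: {', '.join(diff)}"
                )
        self.taxon_set = reference

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)

    def __getitem__(self, idx: int) -> Tree:
        return self.trees[idx]


@dataclass(frozen=True)
class NodeQuery:
    """A named internal node addressed as the MRCA of a taxon set.

    MRCA addressing keeps "the same node" well defined across the differing
    topologies of a posterior sample.
    """

    name: str
    taxon_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon_set", frozenset(self.taxon_set))
        if len(self.taxon_set) < 2:
            raise TreeError(f"node query {self.name!r} needs at least 2 taxa")


# ---------------------------------------------------------------------------
# conversion from dendropy


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def _convert(dnode) -> TreeNode:
        label = None
        if dnode.is_leaf():
            if dnode.taxon is not None:
                label = dnode.taxon.label
            else:
                label = dnode.label
        node = TreeNode(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(_convert(dchild))
        return node

    root = _convert(dtree.seed_node)
    root.length = None  # root edge length carries no information here
    try:
        return Tree(root)
    except TreeError as exc:
        raise TreeError(f"invalid tree: {exc}") from exc


def parse_newick(text: str) -> Tree:
    """Parse a single rooted Newick tree with branch lengths.

    Basal polytomies are read as root polytomies; the tree is treated as
    rooted exactly as written.  Absent or negative branch lengths are errors.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"Newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def _looks_like_nexus(text: str) -> bool:
    return text.lstrip()[:6].upper() == "#NEXUS"


def read_tree_sample(path, format: str | None = None, provenance: str | None = None) -> TreeSample:
    """Read a tree sample from a Newick list (one tree per line) or a NEXUS
    trees block (translate table honoured, square-bracket comments stripped).

    ``format`` is ``"newick-list"``, ``"nexus"``, or None to sniff from the
    file header.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if format is None:
        format = "nexus" if _looks_like_nexus(text) else "newick-list"
    schema = {"newick-list": "newick", "nexus": "nexus"}.get(format)
    if schema is None:
        raise TreeError(f"unknown tree sample format {format!r}")
    try:
        dtrees = dendropy.TreeList.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"failed to read tree sample from {path}: {exc}") from exc
    if len(dtrees) == 0:
        raise TreeError(f"no trees found in {path}")
    trees = [_from_dendropy(dt) for dt in dtrees]
    return TreeSample(trees, provenance=provenance or str(path))


def write_tree_sample(sample: TreeSample, path, format: str = "newick-list") -> None:
    """Write a tree sample as a Newick list (one tree per line) or as a
    NEXUS trees block with a translate table."""
    if format == "newick-list":
        with open(path, "w", encoding="utf-8") as fh:
            for tree in sample:
                fh.write(tree.to_newick() + "\n")
        return
    if format != "nexus":
        raise TreeError(f"unknown tree sample format {format!r}")
    taxa = sorted(sample.taxon_set)
    number = {t: str(i + 1) for i, t in enumerate(taxa)}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#NEXUS\nbegin trees;\n  translate\n")
        fh.write(",\n".join(f"    {number[t]} {_nexus_quote(t)}" for t in taxa))
        fh.write(";\n")
        for i, tree in enumerate(sample):
            renamed = tree.copy()
            for tip in renamed.tips():
                tip.label = number[tip.label]
            fh.write(f"  tree sample_{i + 1} = {renamed.to_newick()}\n")
        fh.write("end;\n")


def _nexus_quote(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,'\"=]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# tree operations


def prune_taxa(tree: Tree, drop: Iterable[str]) -> Tree:
    """Remove the named tips and tidy the topology.

    Degree-2 internal nodes left behind are collapsed with their branch
    lengths summed; if the root is left with a single child, that child
    becomes the new root (its subtending branch length is discarded).
    """
    drop = set(drop)
    taxa = tree.taxa
    unknown = drop - taxa
    if unknown:
        raise TreeError(f"cannot prune unknown taxa: {', '.join(sorted(unknown))}")
    if drop == taxa:
        raise TreeError("cannot prune every taxon from the tree")

    work = tree.copy()

    # remove dropped tips, then repeatedly clean up empty internals
    for node in list(work.postorder()):
        if node.is_tip and node.label in drop:
            node.parent.children.remove(node)

    def _cleanup(node: TreeNode) -> TreeNode:
        node.children = [_cleanup(c) for c in node.children if _subtree_has_tip(c)]
        # collapse unary internals below the root
        new_children = []
        for child in node.children:
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                grand.parent = node
                child = grand
            child.parent = node
            new_children.append(child)
        node.children = new_children
        return node

    def _subtree_has_tip(node: TreeNode) -> bool:
        if node.is_tip:
            return node.label is not None
        return any(_subtree_has_tip(c) for c in node.children)

    root = _cleanup(work.root)
    while len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    return Tree(root)


def mrca(tree: Tree, taxon_set: Iterable[str]) -> TreeNode:
    """Most recent common ancestor of a set of tips.

    Found by post-order accumulation of tip sets: the deepest node whose
    clade contains every queried taxon.
    """
    query = set(taxon_set)
    taxa = tree.taxa
    for t in query:
        if t not in taxa:
            raise TreeError(f"unknown taxon {t!r} in MRCA query")
    if not query:
        raise TreeError("empty MRCA query")

    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            tipset = {node.label} & query
        else:
            tipset = set()
            for child in node.children:
                tipset |= below.pop(id(child))
        if tipset == query:
            return node
        below[id(node)] = tipset
    raise TreeError("MRCA not found")  # pragma: no cover - unreachable on valid input


def kappa_transform(tree: Tree, kappa: float) -> Tree:
    """Raise every branch length to the power κ (topology unchanged).

    κ=1 leaves the tree untouched; κ=0 sets every branch to length 1, making
    the expected amount of change independent of the original branch
    lengths.  0**0 is defined as 1.
    """
    if not (kappa >= 0):  # also rejects NaN
        raise TreeError(f"kappa must be finite and >= 0, got {kappa}")
    out = tree.copy()
    for node in out.postorder():
        if node is not out.root:
            node.length = float(node.length) ** kappa
    return out
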