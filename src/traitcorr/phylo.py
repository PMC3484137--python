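"""Rooted phylogenies, tree samples, and node resolution.

Trees are stored in a flat array representation (parent pointers, branch
lengths, labels) that the likelihood machinery can consume directly.
Parsing of Newick and NEXUS TREES blocks is delegated to dendropy; this
module adds the validation the downstream analyses rely on (single root,
unique non-empty leaf labels, non-negative branch lengths, shared taxon
sets across a tree sample).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeSample",
    "NodeQuery",
    "PhyloParseError",
    "parse_newick",
    "parse_trees_block",
    "resolve_node",
]


class PhyloParseError(ValueError):
    """Raised for malformed tree input or invariant violations."""


@dataclass(frozen=True)
class NodeQuery:
    """A node addressed as the MRCA of two or more taxa.

    ``name`` is an optional display label (e.g. ``"node 23"``) carried
    through to report rows; it plays no role in resolution.
    """

    labels: frozenset[str]
    name: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "labels", frozenset(self.labels))
        if len(self.labels) < 2:
            raise ValueError("NodeQuery needs at least two taxon labels")

    @property
    def display(self) -> str:
        return self.name or "mrca(" + ",".join(sorted(self.labels)) + ")"


class Phylogeny:
    """A rooted tree with branch lengths over labelled leaves.

    Parameters
    ----------
    parent : sequence of int
        Parent index per node; exactly one entry must be -1 (the root).
    lengths : sequence of float
        Branch length above each node (ignored for the root).
    labels : sequence of str or None
        Leaf labels; internal nodes may be None.
    """

    def __init__(self, parent: Sequence[int], lengths: Sequence[float],
                 labels: Sequence[str | None], validate: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.shape[0]
        if self.lengths.shape[0] != n or len(self.labels) != n:
            raise ValueError("parent, lengths and labels must have equal length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[int(p)].append(i)
        if validate:
            if len(roots) != 1:
                raise PhyloParseError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.lengths[self.root] = 0.0
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        if validate:
            self._validate()
        self.postorder = self._postorder()
        self.leaf_index = {self.labels[i]: i for i in range(n) if self.is_leaf[i]}

    def _validate(self):
        for i in range(self.n_nodes):
            if self.is_leaf[i] and not self.labels[i]:
                raise PhyloParseError(f"leaf node {i} has no label")
            if i != self.root and self.lengths[i] < 0:
                raise PhyloParseError(
                    f"negative branch length {self.lengths[i]} above node "
                    f"{self.labels[i] or i}")
        leaves = [self.labels[i] for i in range(self.n_nodes) if self.is_leaf[i]]
        if len(set(leaves)) != len(leaves):
            dup = sorted({x for x in leaves if leaves.count(x) > 1})
            raise PhyloParseError(f"duplicate leaf labels: {dup}")

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.asarray(order, dtype=np.int64)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.leaf_index)

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_leaf[i]]

    def mrca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor (node index) of the given leaf labels."""
        labels = list(labels)
        idx = []
        for lab in labels:
            if lab not in self.leaf_index:
                raise KeyError(f"unknown taxon label: {lab!r}")
            idx.append(self.leaf_index[lab])
        paths = []
        for i in idx:
            path = []
            while i >= 0:
                path.append(i)
                i = int(self.parent[i])
            paths.append(path[::-1])  # root ... leaf
        k = 0
        while all(len(p) > k for p in paths) and len({p[k] for p in paths}) == 1:
            k += 1
        return paths[0][k - 1]

    def rescale(self, total_length: float) -> "Phylogeny":
        """Return a copy with branch lengths scaled to the given total."""
        cur = float(self.lengths.sum())
        if cur <= 0:
            raise ValueError("cannot rescale a tree of zero total length")
        lengths = self.lengths * (total_length / cur)
        return Phylogeny(self.parent.copy(), lengths, list(self.labels))

    def to_newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf[i]:
                core = self.labels[i]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
                if self.labels[i]:
                    core += self.labels[i]
            if i == self.root:
                return core
            return f"{core}:{self.lengths[i]:.10g}"
        return fmt(self.root) + ";"

    def __repr__(self):
        return f"<Phylogeny with {self.n_leaves} leaves, {self.n_nodes} nodes>"

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        for nd in nodes:
            parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
            el = nd.edge.length
            lengths.append(0.0 if el is None else float(el))
            if nd.taxon is not None:
                labels.append(str(nd.taxon.label))
            elif nd.label:
                labels.append(str(nd.label))
            else:
                labels.append(None)
        return cls(parent, lengths, labels)


@dataclass
class TreeSample:
    """An ordered collection of rooted trees over one shared taxon set."""

    trees: list[Phylogeny] = field(default_factory=list)

    def __post_init__(self):
        if not self.trees:
            raise PhyloParseError("TreeSample must contain at least one tree")
        taxa = self.trees[0].taxa
        for k, t in enumerate(self.trees[1:], start=2):
            if t.taxa != taxa:
                missing = sorted(taxa ^ t.taxa)
                raise PhyloParseError(
                    f"tree {k} has a different taxon set (symmetric difference: {missing})")

    @property
    def taxa(self) -> frozenset[str]:
        return self.trees[0].taxa

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


def _dendropy_get(text: str, schema: str):
    try:
        if schema == "newick":
            return dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        return dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises a zoo of error classes
        raise PhyloParseError(f"could not parse {schema} input: {exc}") from exc


def parse_newick(text: str | io.TextIOBase) -> Phylogeny:
    """Parse a single rooted Newick statement (';'-terminated).

    Unlabelled internal nodes are given synthetic identifiers by position.
    Raises :class:`PhyloParseError` for malformed input, duplicate leaf
    labels, or negative branch lengths.
    """
    if hasattr(text, "read"):
        text = text.read()
    text = text.strip()
    if not text.endswith(";"):
        raise PhyloParseError("Newick statement must be terminated by ';'")
    return Phylogeny.from_dendropy(_dendropy_get(text, "newick"))


def parse_trees_block(text: str | io.TextIOBase) -> TreeSample:
    """Parse a NEXUS TREES block (TRANSLATE table honoured) into a TreeSample."""
    if hasattr(text, "read"):
        text = text.read()
    tl = _dendropy_get(text, "nexus")
    if len(tl) == 0:
        raise PhyloParseError("no trees found in NEXUS TREES block")
    return TreeSample([Phylogeny.from_dendropy(t) for t in tl])


def resolve_node(tree: Phylogeny, query: NodeQuery) -> int:
    """Resolve a NodeQuery to the MRCA node index in this tree."""
    return tree.mrca(query.labels)
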