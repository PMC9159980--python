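"""Phylogenetic tree I/O and tree-derived quantities.

Trees are rooted, have branch lengths in time units, and are held in a light
array-based structure (:class:`PhyloTree`).  Parsing and serialization of
Newick/Nexus go through :mod:`dendropy`; everything downstream of parsing —
validation, ultrametricity checks, unit-height scaling, the Brownian-motion
correlation matrix, clade keys, subtree extraction — is implemented here.

The Brownian correlation matrix is the standard phylogenetic GLS structure:
under Brownian motion on an ultrametric tree of height *T*, the covariance of
a trait between two tips is proportional to the root-to-MRCA path length, so
the correlation is that shared path divided by *T*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeSample",
    "TreeError",
    "parse_newick",
    "write_newick",
    "to_unit_height",
    "phylo_correlation",
    "clade_keys",
    "read_tree_sample",
    "parse_tree_sample",
    "extract_subtree",
]

#: relative tolerance for ultrametricity checks
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed, inconsistent, or non-ultrametric trees."""


@dataclass
class PhyloTree:
    """Rooted phylogeny as parallel arrays indexed by node id.

    Node 0..n_nodes-1; ``parent[root] == -1`` and ``length[root] == 0``.
    ``label[i]`` is the taxon name for tips and ``None`` (or a support label)
    for internal nodes.
    """

    parent: np.ndarray
    length: np.ndarray
    label: list
    children: list = field(repr=False)
    root: int = 0

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def internal_ids(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[i] for i in self.tip_ids]

    def postorder(self) -> list[int]:
        """Node ids, children always before parents."""
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.length[v]
        return d

    def height(self) -> float:
        """Maximum root-to-tip depth."""
        d = self.depths()
        return float(max(d[i] for i in self.tip_ids))

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()
        tips = [d[i] for i in self.tip_ids]
        h = max(tips)
        return h == 0 or (h - min(tips)) <= rtol * h

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            length=self.length.copy(),
            label=list(self.label),
            children=[list(c) for c in self.children],
            root=self.root,
        )

    def validate(self) -> None:
        if (self.length < 0).any():
            raise TreeError("negative branch length")
        roots = [i for i in range((self.n_nodes)) if self.parent[i] < 0]
        if roots != [self.root]:
            raise TreeError(f"expected exactly one root, found nodes {roots}")
        labels = self.tip_labels
        if any(lb is None or lb == "" for lb in labels):
            raise TreeError("unlabeled tip")
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        if dupes:
            raise TreeError(f"duplicate tip label(s): {', '.join(dupes)}")

    def mrca(self, taxa: Iterable[str]) -> int:
        """Node id of the most recent common ancestor of the named tips."""
        want = set(taxa)
        below: dict[int, set] = {}
        for v in self.postorder():
            if not self.children[v]:
                below[v] = {self.label[v]}
            else:
                below[v] = set().union(*(below[c] for c in self.children[v]))
            if want <= below[v]:
                return v
        raise TreeError(f"taxa not all present in tree: {sorted(want)}")


@dataclass
class TreeSample:
    """Ordered collection of trees over one shared taxon set."""

    trees: list
    taxa: frozenset

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


# --------------------------------------------------------------------- parse
def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    length = np.zeros(n)
    label: list = [None] * n
    children: list = [[] for _ in range(n)]
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else "(internal node)"
                raise TreeError(f"missing branch length on edge above {who!r}")
            length[i] = float(nd.edge.length)
        if nd.taxon is not None:
            label[i] = nd.taxon.label.strip()
        elif nd.label is not None:
            label[i] = str(nd.label).strip()
    tree = PhyloTree(parent=parent, length=length, label=label, children=children, root=0)
    tree.validate()
    return tree


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a validated :class:`PhyloTree`.

    Raises :class:`TreeError` naming the problem for malformed input,
    duplicate tip labels, or missing branch lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with 17 significant digits (round-trips branch lengths)."""

    def rec(v: int) -> str:
        if not tree.children[v]:
            s = tree.label[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        if tree.parent[v] >= 0:
            s += f":{tree.length[v]:.17g}"
        return s

    return rec(tree.root) + ";"


def parse_tree_sample(text: str) -> TreeSample:
    """Parse a multi-tree Newick or Nexus document into a :class:`TreeSample`.

    All trees must share the same tip-label set; the first offending tree is
    reported by its 1-based index.
    """
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    try:
        dtrees = dendropy.TreeList.get(
            data=text, schema=schema, preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"malformed tree file ({schema}): {exc}") from exc
    if len(dtrees) == 0:
        raise TreeError("tree file contains no trees")
    trees = [_from_dendropy(t) for t in dtrees]
    taxa = frozenset(trees[0].tip_labels)
    for i, t in enumerate(trees[1:], start=2):
        if frozenset(t.tip_labels) != taxa:
            raise TreeError(
                f"tree {i} has a different taxon set than tree 1: "
                f"{sorted(frozenset(t.tip_labels) ^ taxa)}"
            )
    return TreeSample(trees=trees, taxa=taxa)


def read_tree_sample(path) -> TreeSample:
    with open(path) as fh:
        return parse_tree_sample(fh.read())


# ----------------------------------------------------------------- transform
def to_unit_height(tree: PhyloTree) -> PhyloTree:
    """Rescale all branch lengths so the root-to-tip height is exactly 1.

    The tree must be ultrametric within ``ULTRAMETRIC_RTOL`` relative
    tolerance; otherwise a :class:`TreeError` reports the depth discrepancy.
    """
    d = tree.depths()
    tips = np.array([d[i] for i in tree.tip_ids])
    h = tips.max()
    if h <= 0:
        raise TreeError("tree has zero height")
    if (h - tips.min()) > ULTRAMETRIC_RTOL * h:
        raise TreeError(
            f"tree is not ultrametric: tip depths range "
            f"[{tips.min():.6g}, {tips.max():.6g}] "
            f"(max discrepancy {h - tips.min():.6g})"
        )
    out = tree.copy()
    out.length = out.length / h
    return out


def phylo_correlation(tree: PhyloTree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion correlation matrix for the requested tips.

    Entry (i, j) is the root-to-MRCA path length of taxa i and j divided by
    the tree height; the diagonal is 1.  Requires an ultrametric tree.
    """
    if not tree.is_ultrametric():
        raise TreeError("phylo_correlation requires an ultrametric tree")
    tips = {tree.label[i]: i for i in tree.tip_ids}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise TreeError(f"taxa not in tree: {missing}")
    col = {t: k for k, t in enumerate(taxa)}
    d = tree.depths()
    h = tree.height()
    m = len(taxa)
    R = np.zeros((m, m))
    # At each internal node, pairs of requested tips drawn from different
    # child subtrees have that node as their MRCA.
    below: dict[int, list] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            lb = tree.label[v]
            below[v] = [col[lb]] if lb in col else []
        else:
            groups = [below[c] for c in tree.children[v]]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            R[a, b] = R[b, a] = d[v] / h
            below[v] = [x for g in groups for x in g]
    np.fill_diagonal(R, 1.0)
    return R


def clade_keys(tree: PhyloTree) -> dict:
    """Map internal node id -> frozenset of descendant tip labels.

    Clade keys are how nodes are matched across trees with differing
    topologies (by content, not by index).
    """
    out: dict[int, frozenset] = {}
    below: dict[int, set] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            below[v] = {tree.label[v]}
        else:
            below[v] = set().union(*(below[c] for c in tree.children[v]))
            out[v] = frozenset(below[v])
    return out


def extract_subtree(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced subtree on a taxon subset.

    Unary internal nodes left by pruning are collapsed, with branch lengths
    summed, so the result is the minimal rooted tree connecting the taxa
    (rooted at their MRCA).
    """
    keep = set(taxa)
    have = set(tree.tip_labels)
    missing = keep - have
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise TreeError("need at least two taxa for a subtree")

    # children-of-kept map in the induced topology
    kept_children: dict[int, list] = {}
    kept_node: dict[int, bool] = {}
    for v in tree.postorder():
        if not tree.children[v]:
            kept_node[v] = tree.label[v] in keep
            kept_children[v] = []
        else:
            sub = [c for c in tree.children[v] if kept_node[c]]
            kept_node[v] = len(sub) > 0
            kept_children[v] = sub

    # find the new root: first node (from the old root down) with >= 2 kept children
    new_root = tree.root
    while len(kept_children[new_root]) == 1:
        new_root = kept_children[new_root][0]

    parent: list[int] = []
    length: list[float] = []
    label: list = []
    children: list = []

    def build(v: int, parent_id: int) -> None:
        """Add node v (collapsing unary chains below it) under parent_id."""
        blen = float(tree.length[v])
        while len(kept_children[v]) == 1 and tree.children[v]:
            v = kept_children[v][0]
            blen += float(tree.length[v])
        my_id = len(parent)
        parent.append(parent_id)
        length.append(blen if parent_id >= 0 else 0.0)
        label.append(tree.label[v])
        children.append([])
        if parent_id >= 0:
            children[parent_id].append(my_id)
        for c in kept_children[v]:
            build(c, my_id)

    build(new_root, -1)
    out = PhyloTree(
        parent=np.array(parent, dtype=int),
        length=np.array(length, dtype=float),
        label=label,
        children=children,
        root=0,
    )
    out.validate()
    return out
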