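"""Rooted time-calibrated trees: parsing, coercion, pruning, node ages.

The in-memory representation is a flat array-based :class:`PhyloTree` —
tips occupy indices ``0..ntips-1``, internal nodes follow, and every
likelihood engine in this package walks the cached postorder.  Branch
lengths are in millions of years (My); node ages are measured backward
from the present, so tips of an ultrametric tree sit at age 0.

Newick text is parsed and written through dendropy; quoted labels and
internal-node labels are supported, NHX annotations are not.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "TreeError",
    "parse_newick",
    "write_newick",
    "resolve_polytomies",
    "force_ultrametric",
    "drop_tips",
    "node_ages",
]

ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed newick input or invalid tree operations."""


@dataclass
class PhyloTree:
    """Rooted phylogeny with branch lengths in My.

    Attributes
    ----------
    parent : (n_nodes,) int array; ``parent[root] == -1``.
    lengths : (n_nodes,) float array; ``lengths[i]`` is the branch above
        node *i* (0.0 for the root).
    tip_labels : list of unique strings for nodes ``0..ntips-1``.
    node_labels : optional labels for internal nodes (parallel to nodes,
        empty string where absent).
    """

    parent: np.ndarray
    lengths: np.ndarray
    tip_labels: list[str]
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        if np.any(self.lengths < 0):
            raise TreeError("negative branch length")
        if not self.node_labels:
            self.node_labels = [""] * self.n_nodes
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dup = sorted({x for x in self.tip_labels if self.tip_labels.count(x) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise TreeError(f"tree must have exactly one root, found {roots.size}")
        self._children: list[list[int]] | None = None
        self._postorder: np.ndarray | None = None

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self, node: int) -> list[int]:
        return self.children_map()[node]

    def children_map(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def postorder(self) -> np.ndarray:
        """Node indices, every child before its parent."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            ch = self.children_map()
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(ch[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def tip_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def subtree_tips(self, node: int) -> list[int]:
        """Tip indices below (and including) ``node``."""
        out, stack, ch = [], [node], self.children_map()
        while stack:
            v = stack.pop()
            if self.is_tip(v):
                out.append(v)
            stack.extend(ch[v])
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(), self.lengths.copy(), list(self.tip_labels), list(self.node_labels)
        )


# -- newick I/O ----------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    tips = [n for n in nodes if n.is_leaf()]
    internals = [n for n in nodes if not n.is_leaf()]
    index: dict[int, int] = {}
    tip_labels = []
    for i, n in enumerate(tips):
        index[id(n)] = i
        tip_labels.append(n.taxon.label if n.taxon else (n.label or f"t{i}"))
    for j, n in enumerate(internals):
        index[id(n)] = len(tips) + j
    n_nodes = len(nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    lengths = np.zeros(n_nodes)
    node_labels = [""] * n_nodes
    for n in nodes:
        i = index[id(n)]
        if n.parent_node is not None:
            parent[i] = index[id(n.parent_node)]
            lengths[i] = float(n.edge.length) if n.edge.length is not None else 0.0
        if not n.is_leaf() and n.label:
            node_labels[i] = n.label
    return PhyloTree(parent, lengths, tip_labels, node_labels)


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Raises :class:`TreeError` on malformed input (with the offending
    token where dendropy reports one) or duplicate tip labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if tree.n_tips < 2:
        raise TreeError("tree must have at least 2 tips")
    return tree


def write_newick(tree: PhyloTree) -> str:
    """Serialize with full precision (round-trips to 1e-12)."""

    def rec(v: int) -> str:
        ch = tree.children(v)
        if not ch:
            lab = tree.tip_labels[v]
            if any(c in lab for c in "(),:;[] \t'"):
                lab = "'" + lab.replace("'", "''") + "'"
            body = lab
        else:
            body = "(" + ",".join(rec(c) for c in ch) + ")" + (tree.node_labels[v] or "")
        if tree.parent[v] >= 0:
            body += f":{tree.lengths[v]:.17g}"
        return body

    return rec(tree.root) + ";"


def read_newick_file(path: str) -> PhyloTree:
    with io.open(path) as fh:
        tree = parse_newick(fh.read())
    logging.getLogger(__name__).info(
        "loaded %s: %d tips, height %.3f", path, tree.n_tips, tree.height)
    return tree


def write_newick_file(tree: PhyloTree, path: str) -> None:
    with io.open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# -- coercion operations -------------------------------------------------


def resolve_polytomies(tree: PhyloTree, seed: int = 0) -> PhyloTree:
    """Make the tree fully binary by inserting zero-length branches.

    Children of each polytomy are combined pairwise in a seeded random
    order, so the same seed gives the same resolution.
    """
    rng = np.random.default_rng(seed)
    ch = [list(c) for c in tree.children_map()]
    parent = list(tree.parent)
    lengths = list(tree.lengths)
    node_labels = list(tree.node_labels)
    for v in range(tree.n_nodes):
        kids = ch[v]
        if len(kids) <= 2:
            continue
        kids = [kids[i] for i in rng.permutation(len(kids))]
        while len(kids) > 2:
            a, b = kids.pop(), kids.pop()
            new = len(parent)
            parent.append(v)
            lengths.append(0.0)
            node_labels.append("")
            parent[a] = new
            parent[b] = new
            kids.append(new)
    out = PhyloTree(
        np.array(parent), np.array(lengths), list(tree.tip_labels), node_labels
    )
    return out


def is_binary(tree: PhyloTree) -> bool:
    return all(len(c) in (0, 2) for c in tree.children_map())


def force_ultrametric(tree: PhyloTree) -> PhyloTree:
    """Extend terminal branches so every tip reaches the maximum depth.

    Topology and internal branch lengths are untouched; no root-to-tip
    path is ever shortened.
    """
    out = tree.copy()
    depths = out.depths()
    h = depths[: out.n_tips].max()
    ext = h - depths[: out.n_tips]
    new = out.lengths[: out.n_tips] + ext
    if np.any(new < 0):
        raise TreeError("ultrametric coercion produced a negative branch")
    out.lengths[: out.n_tips] = new
    return out


def drop_tips(tree: PhyloTree, labels) -> PhyloTree:
    """Remove the named tips; suppress resulting unary nodes.

    Path lengths among survivors are conserved (suppressed nodes donate
    their branch lengths to the surviving path).  The root is retained
    even if left with a single child, so root-to-tip distances of
    survivors are unchanged.
    """
    labels = set(labels)
    idx = tree.tip_index()
    unknown = labels - set(idx)
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if not labels:
        return tree.copy()
    drop = {idx[l] for l in labels}
    keep_tip = [i for i in range(tree.n_tips) if i not in drop]
    if len(keep_tip) < 2:
        raise TreeError("fewer than 2 tips would remain")

    # mark nodes with >=1 surviving descendant tip
    alive = np.zeros(tree.n_nodes, dtype=bool)
    for t in keep_tip:
        alive[t] = True
    for v in tree.postorder():
        if not tree.is_tip(v):
            alive[v] = any(alive[c] for c in tree.children(v))

    root = tree.root
    # new parent/length by walking up through dead/unary nodes
    ch_alive: list[list[int]] = [[] for _ in range(tree.n_nodes)]
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and alive[v]:
            ch_alive[p].append(v)

    keep_node: list[int] = []
    for v in tree.postorder():
        if not alive[v]:
            continue
        if tree.is_tip(v) or v == root or len(ch_alive[v]) >= 2:
            keep_node.append(v)
    keep_set = set(keep_node)

    # map each kept node to nearest kept ancestor, summing lengths;
    # tips come first in original tip order
    tips_sorted = [v for v in keep_node if tree.is_tip(v)]
    tips_sorted.sort()
    internals = [v for v in keep_node if not tree.is_tip(v)]
    order = tips_sorted + internals
    new_index = {v: i for i, v in enumerate(order)}

    parent = np.full(len(order), -1, dtype=np.int64)
    lengths = np.zeros(len(order))
    node_labels = [""] * len(order)
    for v in order:
        if not tree.is_tip(v):
            node_labels[new_index[v]] = tree.node_labels[v]
        if v == root:
            continue
        u, acc = v, tree.lengths[v]
        p = tree.parent[u]
        while p != -1 and p not in keep_set:
            acc += tree.lengths[p]
            p = tree.parent[p]
        parent[new_index[v]] = new_index[p]
        lengths[new_index[v]] = acc
    return PhyloTree(parent, lengths, [tree.tip_labels[v] for v in tips_sorted], node_labels)


def node_ages(tree: PhyloTree, rtol: float = ULTRAMETRIC_RTOL) -> np.ndarray:
    """Ages (My before present) of all nodes of an ultrametric tree.

    Tips are pinned to exactly 0; errors if tip depths spread by more
    than ``rtol``·height.
    """
    depths = tree.depths()
    h = depths[: tree.n_tips].max()
    if h <= 0:
        raise TreeError("tree has zero height")
    if (h - depths[: tree.n_tips].min()) > rtol * h:
        raise TreeError("tree is not ultrametric within tolerance")
    ages = h - depths
    ages[: tree.n_tips] = 0.0
    return ages
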