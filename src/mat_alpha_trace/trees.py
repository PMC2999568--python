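"""Phylogenetic tree container with newick I/O and bipartition queries.

Trees are stored rooted for traversal convenience; an unrooted binary
tree is represented by a root of degree 3 (all other internal nodes
degree 3, i.e. two children). Edge supports (LR-ELW percents) live on the
child node of each internal edge and are written as internal node labels
in newick output, the dialect used by most tree viewers.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]


class PhyloTree:
    """A (rooted or unrooted) phylogenetic tree over named leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf names")

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        import skbio

        sk = skbio.TreeNode.read(io.StringIO(newick), convert_underscores=False)

        def convert(n) -> TreeNode:
            node = TreeNode(
                name=n.name if n.is_tip() else None,
                length=float(n.length) if n.length is not None else 0.0,
                children=[convert(c) for c in n.children],
            )
            if not n.is_tip() and n.name:
                try:
                    node.support = float(n.name)
                except ValueError:
                    pass
            return node

        return cls(convert(sk))

    def to_newick(self, include_supports: bool = False) -> str:
        def render(n: TreeNode) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(render(c) for c in n.children)
            label = ""
            if include_supports and n.support is not None:
                label = f"{n.support:.4g}"
            return f"({inner}){label}:{n.length:.10g}"

        inner = ",".join(render(c) for c in self.root.children)
        label = ""
        if include_supports and self.root.support is not None:
            label = f"{self.root.support:.4g}"
        return f"({inner}){label};"

    def copy(self) -> "PhyloTree":
        return PhyloTree(copy.deepcopy(self.root))

    # -- basic queries ----------------------------------------------------

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def postorder(self) -> Iterator[TreeNode]:
        return self.root.postorder()

    def edges(self) -> Iterator[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs; the child carries the edge length."""
        for parent in self.root.preorder():
            for child in parent.children:
                yield parent, child

    def internal_edges(self) -> list[tuple[TreeNode, TreeNode]]:
        return [(p, c) for p, c in self.edges() if not c.is_leaf]

    def total_length(self) -> float:
        return sum(c.length for _, c in self.edges())

    def find_parent(self, node: TreeNode) -> TreeNode | None:
        for parent in self.root.preorder():
            if node in parent.children:
                return parent
        return None

    # -- bipartitions and monophyly ---------------------------------------

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets below each edge (one side of every bipartition)."""
        below: list[frozenset[str]] = []
        for _, child in self.edges():
            below.append(frozenset(child.leaf_names()))
        return below

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        """True iff some edge separates exactly ``taxa`` from the rest.

        Monophyly on an unrooted tree is the existence of the bipartition
        (taxa | complement); the full leaf set and single leaves are
        trivially monophyletic.
        """
        taxa = frozenset(taxa)
        leaves = frozenset(self.leaf_names())
        if not taxa <= leaves:
            raise ValueError(f"taxa not in tree: {sorted(taxa - leaves)}")
        if taxa == leaves or len(taxa) == 1:
            return True
        complement = leaves - taxa
        for side in self.bipartitions():
            if side == taxa or side == complement:
                return True
        return False

    # -- rooting ----------------------------------------------------------

    def reroot_at_internal(self, node: TreeNode) -> "PhyloTree":
        """Re-root (in place) at ``node``; returns the re-rooted view.

        Under a reversible model the likelihood is invariant to this
        re-rooting (Felsenstein's pulley principle).
        """
        if node.is_leaf:
            raise ValueError("can only reroot at an internal node")
        # locate path root -> node, then reverse parent links along it
        path = _path_to(self.root, node)
        if path is None:
            raise ValueError("node not in tree")
        if len(path) == 1:
            return self
        for parent, child in zip(path, path[1:]):
            parent.children.remove(child)
            child.children.append(parent)
            parent.length, child.length = child.length, 0.0
        new = PhyloTree(path[-1])
        new.root.length = 0.0
        return new

    def midpoint_root(self) -> "PhyloTree":
        """Root a copy of the tree at the midpoint of its longest leaf path."""
        tree = self.copy()
        dists, _ = _leaf_distances(tree)
        (a, b), diameter = max(dists.items(), key=lambda kv: kv[1])
        # walk from a toward b accumulating length until crossing half-way
        path = _leaf_path(tree, a, b)
        half = diameter / 2.0
        acc = 0.0
        for upper, lower, length in path:
            if acc + length >= half:
                offset = half - acc  # measured from the `upper` end
                return _root_on_edge(tree, upper, lower, offset)
            acc += length
        return tree

    def unrooted_copy(self) -> "PhyloTree":
        """Copy with the root forced to degree >= 3 (unroot a bifurcating root)."""
        tree = self.copy()
        while len(tree.root.children) == 2:
            a, b = tree.root.children
            keep, fold = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:
                break  # two-leaf tree stays a cherry
            fold.length += keep.length
            tree.root.children = keep.children + [fold]
        return tree


def _path_to(root: TreeNode, target: TreeNode) -> list[TreeNode] | None:
    if root is target:
        return [root]
    for child in root.children:
        sub = _path_to(child, target)
        if sub is not None:
            return [root] + sub
    return None


def _leaf_distances(tree: PhyloTree):
    leaves = [n for n in tree.postorder() if n.is_leaf]
    parent_of = {}
    for p, c in tree.edges():
        parent_of[id(c)] = p
    dists = {}
    for i, la in enumerate(leaves):
        # distance from la to every node by walking to root
        to_root = {}
        node, d = la, 0.0
        while True:
            to_root[id(node)] = d
            if id(node) not in parent_of:
                break
            d += node.length
            node = parent_of[id(node)]
        for lb in leaves[i + 1 :]:
            node, d = lb, 0.0
            while id(node) not in to_root:
                d += node.length
                node = parent_of[id(node)]
            dists[(la.name, lb.name)] = d + to_root[id(node)]
    return dists, parent_of


def _leaf_path(tree: PhyloTree, a: str, b: str):
    """Edges (upper_node, lower_node, length) along the a->b leaf path."""
    nodes = {n.name: n for n in tree.postorder() if n.is_leaf}
    pa = _path_to(tree.root, nodes[a])
    pb = _path_to(tree.root, nodes[b])
    common = 0
    while common < min(len(pa), len(pb)) and pa[common] is pb[common]:
        common += 1
    lca_idx = common - 1
    edges = []
    # a up to LCA: edges traversed child -> parent
    for i in range(len(pa) - 1, lca_idx, -1):
        edges.append((pa[i], pa[i - 1], pa[i].length))
    # LCA down to b
    for i in range(lca_idx, len(pb) - 1):
        edges.append((pb[i], pb[i + 1], pb[i + 1].length))
    return edges


def _root_on_edge(tree: PhyloTree, end_a: TreeNode, end_b: TreeNode, offset: float) -> PhyloTree:
    """Root at a new node ``offset`` from ``end_a`` on the edge a--b.

    Restructures ``tree`` in place and returns the re-rooted view.
    """
    parent_map = {id(c): p for p, c in tree.edges()}
    if parent_map.get(id(end_b)) is end_a:
        parent, child, from_parent = end_a, end_b, offset
    elif parent_map.get(id(end_a)) is end_b:
        parent, child, from_parent = end_b, end_a, end_a.length - offset
    else:
        raise ValueError("ends do not share an edge")
    edge_len = child.length
    from_parent = min(max(from_parent, 0.0), edge_len)
    if parent is not tree.root:
        tree = tree.reroot_at_internal(parent)
    root = tree.root  # is `parent` after rerooting
    root.children.remove(child)
    child.length = edge_len - from_parent
    root.length = from_parent
    return PhyloTree(TreeNode(children=[child, root]))
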