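"""Lightweight rooted/unrooted phylogenetic trees.

The tree object is deliberately minimal: labeled tips, optional non-negative
branch lengths, and a root whose degree distinguishes rooted (two children)
from unrooted (basal trifurcation) representations.  Newick parsing is
delegated to dendropy; writing is a direct recursion so that branch lengths
round-trip at full precision.
"""
from __future__ import annotations

from typing import Iterator

import dendropy

from .errors import ParseError, ValidationError

__all__ = ["Node", "PhyloTree", "read_newick", "write_newick"]


class Node:
    __slots__ = ("parent", "children", "label", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label
        self.length = length  # length of the edge to the parent; None = absent

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length})"


class PhyloTree:
    """A tree with uniquely labeled tips and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root
        labels = [t.label for t in self.tips()]
        if len(set(labels)) != len(labels):
            raise ValidationError("tip labels must be unique")

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    # -- construction helpers ---------------------------------------------
    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            clone = Node(node.label, node.length)
            for child in node.children:
                clone.add_child(rec(child))
            return clone

        return PhyloTree(rec(self.root))

    def find_tip(self, label: str) -> Node:
        for tip in self.tips():
            if tip.label == label:
                return tip
        raise KeyError(label)

    # -- undirected view ---------------------------------------------------
    def adjacency(self) -> dict[Node, list[tuple[Node, float | None]]]:
        adj: dict[Node, list[tuple[Node, float | None]]] = {}
        for node in self.preorder():
            adj.setdefault(node, [])
            for child in node.children:
                adj[node].append((child, child.length))
                adj.setdefault(child, []).append((node, child.length))
        return adj

    # -- output ------------------------------------------------------------
    def to_newick(self, lengths: bool = True) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    body += node.label
            if lengths and node.length is not None and node is not self.root:
                body += f":{format(node.length, '.12g')}"
            return body

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.to_newick()})"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def rec(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    return PhyloTree(rec(dtree.seed_node))


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are optional and recorded as ``None`` when absent.
    Unrooted trees keep their basal trifurcation.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise ParseError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    return tree.to_newick(lengths=lengths)


def root_on_tip_edge(tree: PhyloTree, tip_label: str) -> PhyloTree:
    """Re-root a tree at the midpoint of the pendant edge of ``tip_label``.

    The result is rooted (root of degree 2) with the named tip on one side
    and everything else on the other.  The pendant edge length, when present,
    is split equally; absent lengths stay absent.
    """
    adj = tree.adjacency()
    tip = tree.find_tip(tip_label)
    (neighbor, length), = adj[tip]

    def build(node: Node, parent: Node, edge_len: float | None) -> Node:
        clone = Node(node.label, edge_len)
        for other, ln in adj[node]:
            if other is not parent:
                clone.add_child(build(other, node, ln))
        return clone

    half = None if length is None else length / 2.0
    root = Node()
    root.add_child(Node(tip.label, half))
    root.add_child(build(neighbor, tip, half))
    return PhyloTree(root)


def root_on_outgroup(tree: PhyloTree, outgroup_labels: set[str]) -> PhyloTree:
    """Root on the edge separating ``outgroup_labels`` from all other tips.

    If no single edge induces that bipartition the tree is rooted on the
    pendant edge of the first outgroup tip instead (with the same midpoint
    convention), which is the best available polarization when outgroup
    samples are not monophyletic in the unrooted tree.
    """
    labels = set(tree.tip_labels)
    if not outgroup_labels <= labels:
        missing = outgroup_labels - labels
        raise ValidationError(f"outgroup tips not in tree: {sorted(missing)}")
    if len(outgroup_labels) == 1:
        return root_on_tip_edge(tree, next(iter(outgroup_labels)))

    adj = tree.adjacency()
    ingroup = labels - outgroup_labels

    # search for an edge whose removal splits outgroup from ingroup
    def tipset(node: Node, parent: Node) -> set[str]:
        out = set()
        stack = [(node, parent)]
        while stack:
            cur, par = stack.pop()
            if all(other is par for other, _ in adj[cur]):
                out.add(cur.label)
            for other, _ in adj[cur]:
                if other is not par:
                    stack.append((other, cur))
        return out

    for node in tree.preorder():
        for other, length in adj[node]:
            side = tipset(other, node)
            if side == outgroup_labels or side == ingroup:
                half = None if length is None else length / 2.0

                def build(n: Node, parent: Node, edge_len):
                    clone = Node(n.label, edge_len)
                    for o, ln in adj[n]:
                        if o is not parent:
                            clone.add_child(build(o, n, ln))
                    return clone

                root = Node()
                root.add_child(build(other, node, half))
                root.add_child(build(node, other, half))
                return PhyloTree(root)
    return root_on_tip_edge(tree, sorted(outgroup_labels)[0])
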