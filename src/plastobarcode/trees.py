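"""Leaf-labelled trees with branch lengths.

A minimal rooted container that doubles as an unrooted tree: distance-based
builders return a tree whose root is a basal trifurcation, and all edge-based
queries (bipartitions, path lengths, monophyly) ignore where the root sits.
Newick text is written here; parsing is delegated to dendropy.
"""
from __future__ import annotations

import re
from typing import Iterator

import numpy as np

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["Node"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, length={self.length}, n_children={len(self.children)})"


class Tree:
    """A tree rooted at ``root``; the root's ``length`` is ignored."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ basics
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        names = [n.name for n in self.leaves()]
        if any(n is None for n in names):
            raise ValueError("tree contains unnamed leaves")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")
        return names  # type: ignore[return-value]

    def copy(self) -> "Tree":
        def _copy(node: Node) -> Node:
            new = Node(node.name, node.length)
            for child in node.children:
                new.add(_copy(child))
            return new

        return Tree(_copy(self.root))

    def rescale(self, factor: float) -> "Tree":
        for node in self.root.postorder():
            node.length *= factor
        return self

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    # ------------------------------------------------------------------ newick
    @staticmethod
    def _quote(label: str) -> str:
        if _NEWICK_UNSAFE.search(label):
            return "'" + label.replace("'", "''") + "'"
        return label

    def to_newick(self, precision: int = 12) -> str:
        fmt = f"%.{precision}g"

        def _fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = self._quote(node.name or "")
            else:
                body = "(" + ",".join(_fmt(c, False) for c in node.children) + ")"
                if node.name:
                    body += self._quote(node.name)
            if top:
                return body
            return body + ":" + (fmt % node.length)

        return _fmt(self.root, True) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )

        def _convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label, dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add(_convert(child))
            return node

        return cls(_convert(dt.seed_node))

    # -------------------------------------------------------------- structure
    def bipartitions(self) -> list[frozenset]:
        """Leaf sets below every non-root edge (includes trivial pendant sets)."""
        below: dict[int, frozenset] = {}
        out = []
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is not self.root:
                out.append(below[id(node)])
        return out

    def path_length_matrix(self, order: list[str] | None = None) -> tuple[list[str], np.ndarray]:
        """Patristic distances between all leaf pairs."""
        names = self.leaf_names()
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))
        # distances of leaves below each node to that node
        dist_below: dict[int, dict[int, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                dist_below[id(node)] = {idx[node.name]: 0.0}
            else:
                merged: dict[int, float] = {}
                parts = []
                for child in node.children:
                    part = {k: v + child.length for k, v in dist_below[id(child)].items()}
                    parts.append(part)
                for a in range(len(parts)):
                    for b in range(a + 1, len(parts)):
                        for i, di in parts[a].items():
                            for j, dj in parts[b].items():
                                d[i, j] = d[j, i] = di + dj
                    merged.update(parts[a])
                merged.update(parts[-1])
                dist_below[id(node)] = merged
        if order is not None:
            perm = [names.index(x) for x in order]
            return list(order), d[np.ix_(perm, perm)]
        return names, d

    # ----------------------------------------------------------------- rooting
    def _flip_to_root(self, node: Node) -> None:
        """Reverse parent edges so ``node`` becomes the root (in place)."""
        path = []
        cur = node
        while cur.parent is not None:
            path.append(cur)
            cur = cur.parent
        # cur is the old root; walk from the top of the tree downwards
        for child in reversed(path):
            parent = child.parent
            assert parent is not None
            parent.children.remove(child)
            child.parent = None
            child.add(parent)
            parent.length = child.length
        node.length = 0.0
        self.root = node
        self._suppress_unifurcations()

    def _suppress_unifurcations(self) -> None:
        for node in list(self.root.postorder()):
            if node is self.root or node.is_leaf:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                assert parent is not None
                pos = parent.children.index(node)
                parent.children[pos] = child
                child.parent = parent
        if len(self.root.children) == 1 and not self.root.children[0].is_leaf:
            child = self.root.children[0]
            child.parent = None
            child.length = 0.0
            self.root = child

    def root_with_outgroup(self, label: str) -> "Tree":
        """Return a copy rooted on the midpoint of the outgroup's pendant edge."""
        t = self.copy()
        leaf = t.find_leaf(label)
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot root a single-leaf tree")
        half = leaf.length / 2.0
        parent.children.remove(leaf)
        leaf.parent = None
        t._flip_to_root(parent)
        new_root = Node()
        leaf.length = half
        new_root.add(leaf)
        parent.length = half
        new_root.add(parent)
        t.root = new_root
        t._suppress_unifurcations()
        return t

    def unroot(self) -> "Tree":
        """Return a copy with a degree-2 root suppressed into a trifurcation."""
        t = self.copy()
        if len(t.root.children) != 2:
            return t
        a, b = t.root.children
        if a.is_leaf and b.is_leaf:
            return t  # two-leaf tree cannot be unrooted further
        inner, other = (a, b) if not a.is_leaf else (b, a)
        other.length += inner.length
        inner.parent = None
        inner.length = 0.0
        inner.add(other)
        t.root = inner
        return t


def two_leaf_tree(name_a: str, name_b: str, distance: float) -> Tree:
    """The conventional two-leaf tree: the single edge split at its midpoint."""
    root = Node()
    root.add(Node(name_a, distance / 2.0))
    root.add(Node(name_b, distance / 2.0))
    return Tree(root)
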