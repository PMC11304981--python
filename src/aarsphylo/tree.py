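"""In-memory phylogenetic tree with dual support values.

The tree structure used throughout the package: a mutable rooted (or
notionally unrooted) tree whose internal nodes carry a :class:`SupportPair`
holding SH-aLRT, ultrafast-bootstrap (UFB) and transfer-bootstrap-expectation
(TBE) percentages. Branch lengths are optional everywhere; no analysis in
this package reads them.

Polytomies are legal and preserved; every operation (bipartitions, MRCA,
rerooting, NNI) works on multifurcating trees without resolving them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional


@dataclass
class SupportPair:
    """Per-node support values, each a percentage in [0, 100] or None.

    ``raw`` keeps the original Newick label string so that writing a parsed
    tree reproduces the label byte-for-byte.
    """

    sh_alrt: Optional[float] = None
    ufb: Optional[float] = None
    tbe: Optional[float] = None
    raw: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("sh_alrt", "ufb", "tbe"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")

    def is_empty(self) -> bool:
        return self.sh_alrt is None and self.ufb is None and self.tbe is None


class Node:
    """A tree node. Leaves have a name; internal nodes may carry support."""

    __slots__ = ("parent", "children", "name", "length", "support")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[SupportPair] = None,
    ) -> None:
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.name = name
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

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

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves() if n.name is not None)

    def ancestors(self) -> Iterator["Node"]:
        """Yield parent, grandparent, ... up to the root."""
        node = self.parent
        while node is not None:
            yield node
            node = node.parent

    def copy(self) -> "Node":
        dup = Node(self.name, self.length)
        if self.support is not None:
            dup.support = SupportPair(
                self.support.sh_alrt, self.support.ufb,
                self.support.tbe, self.support.raw,
            )
        for child in self.children:
            dup.add_child(child.copy())
        return dup

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal[{len(self.children)}]"
        return f"<Node {kind} {self.name or ''}>"


@dataclass
class PhyloTree:
    """A phylogenetic tree; ``rooted`` records whether the root is meaningful.

    Invariants enforced by :meth:`validate`: unique nonempty leaf names,
    internal nodes with >= 2 children (the root of an unrooted tree is
    typically a trifurcation), nonnegative branch lengths.
    """

    root: Node
    rooted: bool = True

    def validate(self) -> None:
        names: list[str] = []
        for node in self.root.postorder():
            if node.is_leaf:
                if node is self.root:
                    continue  # degenerate single-leaf tree
                if not node.name:
                    raise ValueError("leaf with empty name")
                names.append(node.name)
            elif node is not self.root and len(node.children) < 2:
                raise ValueError("internal node with fewer than 2 children")
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names: {sorted(dupes)}")

    # -- basic queries ----------------------------------------------------
    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.root.postorder() if not n.is_leaf]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.rooted)

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves."""
        want = set(names)
        if not want:
            raise ValueError("mrca of empty set")
        missing = want - set(self.leaf_names())
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        node_sets: dict[int, set[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                node_sets[id(node)] = {node.name} if node.name in want else set()
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= node_sets[id(c)]
                node_sets[id(node)] = acc
            if node_sets[id(node)] == want:
                return node
        return self.root

    def bipartitions(self, include_trivial: bool = False) -> dict[int, frozenset[str]]:
        """Map id(node) -> leaf-name set below each non-root node (one per edge).

        Trivial edges (single leaves) are included only on request.
        """
        out: dict[int, frozenset[str]] = {}
        below: dict[int, frozenset[str]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
            if node is not self.root and (include_trivial or not node.is_leaf):
                out[id(node)] = below[id(node)]
        return out

    def split_set(self) -> set[frozenset[frozenset[str]]]:
        """Unrooted bipartition set: {side, complement} pairs for internal edges.

        Used for topology comparison that is insensitive to root placement.
        """
        all_leaves = self.leaf_names()
        splits: set[frozenset[frozenset[str]]] = set()
        for side in self.bipartitions().values():
            other = all_leaves - side
            if len(side) >= 2 and len(other) >= 2:
                splits.add(frozenset([side, frozenset(other)]))
        return splits

    # -- topology edits ---------------------------------------------------
    def reroot_on_edge(self, child: Node, position: float = 0.5) -> None:
        """Place the root on the edge above ``child``.

        The edge is split at ``position`` (fraction of its length allotted
        to the child side; presentation only). Edge attributes (length,
        support) stay with their edge when parent/child orientation flips.
        The old root is suppressed if it is left with a single child.
        """
        parent = child.parent
        if parent is None:
            raise ValueError("cannot reroot on the root's own (nonexistent) edge")
        new_root = Node()
        # split the child edge's length between the two new edges
        if child.length is not None:
            child_len = child.length * position
            parent_len = child.length * (1.0 - position)
        else:
            child_len = parent_len = None
        parent.remove_child(child)
        new_root.add_child(child)
        child.length = child_len

        # reverse the path parent -> old root; edge attributes travel with edges
        path: list[Node] = [parent]
        node = parent
        while node.parent is not None:
            path.append(node.parent)
            node = node.parent
        # attributes of edge path[i] -- path[i+1] are stored on path[i]
        edge_attrs = [(n.length, n.support) for n in path[:-1]]
        for i, node in enumerate(path[:-1]):
            upper = path[i + 1]
            upper.remove_child(node)
            node.add_child(upper)
            upper.length, upper.support = edge_attrs[i]
        new_root.add_child(parent)
        parent.length = parent_len
        parent.support = child.support  # both halves of the split edge share it

        old_root = path[-1]
        self.root = new_root
        self.rooted = True
        self._suppress_unary(old_root)

    def _suppress_unary(self, node: Node) -> None:
        """Remove a node left with exactly one child, merging its edge."""
        while node is not None and node is not self.root and len(node.children) == 1:
            (only,) = node.children
            parent = node.parent
            assert parent is not None
            idx = parent.children.index(node)
            parent.children[idx] = only
            only.parent = parent
            if node.length is not None or only.length is not None:
                only.length = (node.length or 0.0) + (only.length or 0.0)
            node = parent
        if node is self.root and len(node.children) == 1:
            (only,) = node.children
            only.parent = None
            self.root = only

    def nni(self, edge_child: Node, swap_index: int = 0) -> None:
        """Nearest-neighbour interchange around the edge above ``edge_child``.

        Swaps one child of ``edge_child`` with one of its siblings.
        ``swap_index`` selects the (child, sibling) pairing deterministically.
        """
        parent = edge_child.parent
        if parent is None or edge_child.is_leaf:
            raise ValueError("NNI needs an internal, non-root edge")
        siblings = [c for c in parent.children if c is not edge_child]
        if not siblings:
            raise ValueError("edge has no sibling subtree")
        pairs = [(a, b) for a in edge_child.children for b in siblings]
        a, b = pairs[swap_index % len(pairs)]
        ia = edge_child.children.index(a)
        ib = parent.children.index(b)
        edge_child.children[ia] = b
        parent.children[ib] = a
        a.parent = parent
        b.parent = edge_child
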