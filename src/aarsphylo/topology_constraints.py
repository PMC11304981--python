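"""Constrained topologies for AU testing of the proto-eukaryotic scenario.

The major eukaryote clade is split into three subclades at its top two
bipartitions (skipping splits that shave off singletons or pairs), and all
15 rooted binary arrangements of the four groups {E1, E2, E3, V} are
enumerated: 3 "original" topologies keep the three eukaryote subclades
monophyletic with the viral clade outside; the other 12 "alternative"
topologies place the viral clade within the eukaryote group. Each topology
is written as a Newick constraint in which every group is a multifurcation
of its members, ready for an external AU-test runner.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .tree import Node, PhyloTree


@dataclass
class CladePartition:
    """Three disjoint eukaryote subclades plus the tips excluded by the
    singleton/pair skip rule."""

    e1: frozenset[str]
    e2: frozenset[str]
    e3: frozenset[str]
    excluded: frozenset[str]
    source_clade: str = ""

    def __post_init__(self) -> None:
        sets = [self.e1, self.e2, self.e3]
        for i, j in combinations(range(3), 2):
            if sets[i] & sets[j]:
                raise ValueError("eukaryote subclades overlap")
        if any(len(s) < 3 for s in sets):
            raise ValueError("each eukaryote subclade needs >= 3 tips")

    @property
    def groups(self) -> dict[str, frozenset[str]]:
        return {"E1": self.e1, "E2": self.e2, "E3": self.e3}


@dataclass
class ConstraintTopology:
    label: str
    newick: str
    klass: str  # original | alternative
    group_tree: tuple  # nested tuples over the group names


def _tipset(node: Node) -> frozenset[str]:
    return node.leaf_names() if not node.is_leaf else frozenset([node.name])


def _usable_split(node: Node) -> tuple[Node, Node, set[str]]:
    """Descend from ``node`` to the first bipartition with both sides > 2
    tips, excluding the tips of any skipped small side along the way."""
    excluded: set[str] = set()
    cur = node
    while True:
        if cur.is_leaf:
            raise ValueError("clade exhausted before a usable bipartition")
        kids = list(cur.children)
        if len(kids) > 2:
            # polytomy: treat the largest child vs the rest as the bipartition
            kids.sort(key=lambda k: (-len(_tipset(k)), tuple(sorted(_tipset(k)))))
            big, rest = kids[0], kids[1:]
            rest_tips = set().union(*(_tipset(k) for k in rest))
            if len(rest_tips) <= 2:
                excluded |= rest_tips
                cur = big
                continue
            synthetic = Node()
            for k in rest:
                synthetic.add_child(k.copy())
            return big, synthetic, excluded
        a, b = kids
        ta, tb = _tipset(a), _tipset(b)
        if len(ta) <= 2 and len(tb) <= 2:
            raise ValueError("both sides of the bipartition are singletons/pairs")
        if len(ta) <= 2:
            excluded |= set(ta)
            cur = b
        elif len(tb) <= 2:
            excluded |= set(tb)
            cur = a
        else:
            return a, b, excluded


def split_top_bipartitions(euk_clade: Node, source_clade: str = "",
                           split_larger: bool = True) -> CladePartition:
    """Separate a eukaryote clade into three subclades at its top two
    bipartitions.

    The clade's own bipartition yields two sides; the larger side (tip
    count; ties by lexicographically smallest leaf name) is split again.
    A bipartition that would shave off one or two tips is skipped: those
    tips join the excluded list and the next-deepest bipartition is used.
    Raises when three subclades of >= 3 tips cannot be formed.
    """
    total = len(_tipset(euk_clade))
    if total < 9:
        raise ValueError(f"need >= 9 tips to form three subclades, got {total}")
    a, b, exc1 = _usable_split(euk_clade)
    ta, tb = _tipset(a), _tipset(b)

    def size_key(node: Node) -> tuple:
        tips = _tipset(node)
        return (-len(tips), min(tips))

    first, second = sorted([a, b], key=size_key)
    if not split_larger:
        first, second = second, first
    try:
        c, d, exc2 = _usable_split(first)
    except ValueError:
        # fall back to splitting the other side
        first, second = second, first
        c, d, exc2 = _usable_split(first)
    e1 = frozenset(_tipset(second))
    e2, e3 = sorted([frozenset(_tipset(c)), frozenset(_tipset(d))],
                    key=lambda s: (min(s), len(s)))
    return CladePartition(e1=e1, e2=e2, e3=e3,
                          excluded=frozenset(exc1 | exc2),
                          source_clade=source_clade)


def _rooted_shapes(labels: Sequence[str]) -> list[tuple]:
    """All rooted binary leaf-labelled tree shapes on ``labels``.

    Represented as nested 2-tuples with a canonical (sorted) child order so
    that duplicates collapse naturally. For 4 labels this yields the
    (2n-3)!! = 15 rooted binary trees.
    """
    labels = sorted(labels)
    if len(labels) == 1:
        return [labels[0]]

    def canon(t) -> tuple:
        return t if isinstance(t, str) else tuple(sorted((canon(t[0]), canon(t[1])), key=repr))

    def build(items: tuple) -> list:
        if len(items) == 1:
            return [items[0]]
        out = []
        rest = items[1:]
        # partitions into {A, B} with items[0] always in A, so each unordered
        # pair of sides is produced exactly once
        for r in range(0, len(rest)):
            for combo in combinations(rest, r):
                side_a = (items[0],) + combo
                side_b = tuple(x for x in rest if x not in combo)
                if not side_b:
                    continue
                for left in build(side_a):
                    for right in build(side_b):
                        out.append(canon((left, right)))
        return out

    seen: dict[tuple, tuple] = {}
    for t in build(tuple(labels)):
        seen[t] = t
    return list(seen.values())


def _clades_of(shape) -> set[frozenset[str]]:
    out: set[frozenset[str]] = set()

    def walk(t) -> frozenset[str]:
        if isinstance(t, str):
            return frozenset([t])
        left, right = walk(t[0]), walk(t[1])
        clade = left | right
        out.add(clade)
        return clade

    walk(shape)
    return out


def enumerate_constraints(partition: CladePartition,
                          viral_leafset: Iterable[str]) -> list[ConstraintTopology]:
    """All 15 rooted binary arrangements of {E1, E2, E3, V} as Newick
    constraints.

    klass = "original" iff the three eukaryote subclades are monophyletic
    (the viral group sits outside them); the remaining 12 are
    "alternative". Group members appear as multifurcations.
    """
    viral = frozenset(viral_leafset)
    for name, tips in partition.groups.items():
        if viral & tips:
            raise ValueError(f"viral leaf set overlaps eukaryote subclade {name}")
    if not viral:
        raise ValueError("empty viral leaf set")
    groups = dict(partition.groups)
    groups["V"] = viral

    def render(t) -> str:
        if isinstance(t, str):
            members = sorted(groups[t])
            if len(members) == 1:
                return members[0]
            return "(" + ",".join(members) + ")"
        return "(" + ",".join(render(x) for x in t) + ")"

    shapes = _rooted_shapes(["E1", "E2", "E3", "V"])
    assert len(shapes) == 15
    out: list[ConstraintTopology] = []
    n_orig = 0
    for shape in sorted(shapes, key=repr):
        clades = _clades_of(shape)
        original = frozenset(["E1", "E2", "E3"]) in clades
        if original:
            n_orig += 1
            label = f"original_{n_orig:02d}"
        else:
            label = f"alternative_{len(out) - n_orig + 1:02d}"
        out.append(ConstraintTopology(
            label=label,
            newick=render(shape) + ";",
            klass="original" if original else "alternative",
            group_tree=shape,
        ))
    return out


def constraints_manifest(topologies: Sequence[ConstraintTopology]) -> str:
    """Manifest TSV: label, klass, file name (label + .nwk)."""
    lines = ["label\tklass\tfile"]
    for t in topologies:
        lines.append(f"{t.label}\t{t.klass}\t{t.label}.nwk")
    return "\n".join(lines) + "\n"
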