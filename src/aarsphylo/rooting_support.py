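"""Rooting at the bacteria/archaea split, support thresholds, and TBE.

Gene trees of enzymes conserved across the three domains of life can be
rooted on the branch separating the major bacterial and archaeal clades.
This module scores every edge of an (effectively unrooted) gene tree for
how cleanly it separates the two prokaryotic domains, places the root on
the best edge, evaluates node support against the study thresholds, and
computes the transfer bootstrap expectation (TBE) from a bootstrap tree
set by exhaustive transfer-distance comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .phylo_io import TaxonAnnotation
from .tree import Node, PhyloTree, SupportPair


@dataclass
class SupportThresholds:
    """Statistical-support cutoffs.

    Defaults: SH-aLRT 80%, ultrafast bootstrap 95%, TBE 70%. ``strict=True``
    switches the comparisons from >= to > for producers that treat the
    printed thresholds as exclusive.
    """

    sh_alrt_min: float = 80.0
    ufb_min: float = 95.0
    tbe_min: float = 70.0
    strict: bool = False

    def __post_init__(self) -> None:
        for name in ("sh_alrt_min", "ufb_min", "tbe_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")

    def _passes(self, value: Optional[float], cutoff: float) -> bool:
        if value is None:
            return False
        return value > cutoff if self.strict else value >= cutoff


@dataclass
class BranchScore:
    """Rooting score for one edge: product of the bacterial fraction on one
    side and the archaeal fraction on the other, best orientation."""

    leafset: frozenset[str]
    score: float
    bacteria_side_fraction: float
    archaea_side_fraction: float


def is_supported(node_or_support, thresholds: SupportThresholds,
                 basis: str = "ufb_shalrt") -> bool:
    """Whether a node counts as statistically supported.

    ``ufb_shalrt`` basis requires both SH-aLRT and UFB to pass; ``tbe``
    requires TBE. Missing values never pass.
    """
    support: Optional[SupportPair]
    if isinstance(node_or_support, Node):
        support = node_or_support.support
    else:
        support = node_or_support
    if support is None:
        return False
    if basis == "ufb_shalrt":
        return (thresholds._passes(support.sh_alrt, thresholds.sh_alrt_min)
                and thresholds._passes(support.ufb, thresholds.ufb_min))
    if basis == "tbe":
        return thresholds._passes(support.tbe, thresholds.tbe_min)
    raise ValueError(f"unknown support basis {basis!r}")


def score_edges(tree: PhyloTree, ann: Mapping[str, TaxonAnnotation]) -> list[tuple[Node, BranchScore]]:
    """Score every edge for bacteria/archaea separation.

    For the edge above ``node`` with sides S (below) and S' (rest), the
    score is max over orientation of (fraction of all bacterial tips on one
    side) x (fraction of all archaeal tips on the other). Non-prokaryote
    tips are ignored.
    """
    all_names = tree.leaf_names()
    bacteria = {n for n in all_names if ann[n].domain == "bacteria"}
    archaea = {n for n in all_names if ann[n].domain == "archaea"}
    if not bacteria or not archaea:
        raise ValueError("cannot root: need at least one bacterial and one archaeal tip")
    scored: list[tuple[Node, BranchScore]] = []
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        side = below[id(node)]
        b_in = len(side & bacteria) / len(bacteria)
        a_in = len(side & archaea) / len(archaea)
        fwd = b_in * (1.0 - a_in)          # bacteria below, archaea above
        rev = (1.0 - b_in) * a_in          # archaea below, bacteria above
        if fwd >= rev:
            score = BranchScore(side, fwd, b_in, 1.0 - a_in)
        else:
            score = BranchScore(side, rev, 1.0 - b_in, a_in)
        scored.append((node, score))
    return scored


def root_at_prok_split(tree: PhyloTree, ann: Mapping[str, TaxonAnnotation],
                       position: float = 0.5) -> PhyloTree:
    """Root a gene tree on the edge best separating bacteria from archaea.

    Ties broken by (1) most balanced prokaryote tip counts across the edge,
    (2) lexicographically smallest sorted leaf-name tuple of the below side.
    Returns a new rooted tree; the input is not modified.
    """
    work = tree.copy()
    scored = score_edges(work, ann)
    all_names = work.leaf_names()
    prok = {n for n in all_names if ann[n].is_prokaryote}

    def tie_key(item: tuple[Node, BranchScore]):
        node, bs = item
        below_prok = len(bs.leafset & prok)
        imbalance = abs(below_prok - (len(prok) - below_prok))
        return (-bs.score, imbalance, tuple(sorted(bs.leafset)))

    best_node, _ = min(scored, key=tie_key)
    work.reroot_on_edge(best_node, position=position)
    work.validate()
    return work


# ---------------------------------------------------------------------------
# Transfer bootstrap expectation
# ---------------------------------------------------------------------------

def _all_sides(tree: PhyloTree) -> list[frozenset[str]]:
    """Leaf sets below every non-root edge, trivial (leaf) edges included."""
    return list(tree.bipartitions(include_trivial=True).values())


def transfer_distance(side: frozenset[str], other_side: frozenset[str],
                      all_leaves: frozenset[str]) -> int:
    """delta(b, b'): symmetric-difference size under the better orientation."""
    d1 = len(side ^ other_side)
    d2 = len(side ^ (all_leaves - other_side))
    return min(d1, d2)


def compute_tbe(ref: PhyloTree, bootstraps: Sequence[PhyloTree]) -> dict[frozenset[str], float]:
    """Transfer bootstrap expectation per internal branch of ``ref``.

    For a branch b with lighter side of size p >= 2:
    ``TBE(b) = 100 * (1 - mean_T [ min_{b' in T} delta(b, b') ] / (p - 1))``
    with the minimum taken over every branch of each bootstrap tree
    (trivial leaf branches included, which caps the distance at p - 1).
    Exhaustive comparison; intended for desk-scale trees.

    Returns a map keyed by the branch's lighter-side leaf-name set. Branch
    TBE values are also written onto ``ref``'s node supports.
    """
    if not bootstraps:
        raise ValueError("need at least one bootstrap tree")
    all_leaves = ref.leaf_names()
    for i, bt in enumerate(bootstraps):
        if bt.leaf_names() != all_leaves:
            raise ValueError(f"bootstrap tree {i} leaf set differs from reference")
    boot_sides = [_all_sides(bt) for bt in bootstraps]
    n = len(all_leaves)
    out: dict[frozenset[str], float] = {}
    below: dict[int, frozenset[str]] = {}
    for node in ref.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is ref.root:
            continue
        side = below[id(node)]
        lighter = side if len(side) <= n - len(side) else all_leaves - side
        p = len(lighter)
        if p < 2:
            continue
        total = 0.0
        for sides in boot_sides:
            total += min(transfer_distance(lighter, s, all_leaves) for s in sides)
        tbe = 100.0 * (1.0 - (total / len(bootstraps)) / (p - 1))
        out[lighter] = tbe
        if node.support is None:
            node.support = SupportPair(tbe=tbe)
        else:
            node.support.tbe = tbe
    return out


def felsenstein_support(ref: PhyloTree, bootstraps: Sequence[PhyloTree]) -> dict[frozenset[str], float]:
    """Classical bootstrap proportion per internal branch (exact matches only)."""
    all_leaves = ref.leaf_names()
    boot_splits = []
    for bt in bootstraps:
        splits = set()
        for s in _all_sides(bt):
            if 2 <= len(s) <= len(all_leaves) - 2:
                splits.add(frozenset([s, frozenset(all_leaves - s)]))
        boot_splits.append(splits)
    out: dict[frozenset[str], float] = {}
    for side in ref.bipartitions().values():
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        lighter = side if len(side) <= len(other) else frozenset(other)
        key = frozenset([side, frozenset(other)])
        count = sum(1 for splits in boot_splits if key in splits)
        out[lighter] = 100.0 * count / len(bootstraps)
    return out


def tbe_table(tbe: Mapping[frozenset[str], float]) -> str:
    """Render a per-branch TBE TSV: branch id = sorted lighter-side names '|'-joined."""
    lines = ["branch\ttbe"]
    for side in sorted(tbe, key=lambda s: (len(s), tuple(sorted(s)))):
        lines.append(f"{'|'.join(sorted(side))}\t{tbe[side]:.4g}")
    return "\n".join(lines) + "\n"
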