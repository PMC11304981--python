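"""Evolution inside the viral clades: vHGT, displacement, richness, loss.

Virus-to-virus HGT (vHGT) candidates are minority tips inside gene-tree
clades dominated by one virus order (or by the aaRS-rich clade of
Imitervirales). Displacement calls compare each genome's gene-tree context
(main viral clade vs embedded among eukaryotes or prokaryotes) with the
majority context of its nearest neighbours on the species tree. Richness
profiles count aaRS classes per genome and per species-tree clade and flag
putative recent losses.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .clade_classifier import ViralClade
from .phylo_io import TaxonAnnotation
from .preprocess import AarsCall
from .tree import Node, PhyloTree

GENE_CONTEXTS = ("main_viral", "eukaryote_embedded", "prokaryote_embedded")


@dataclass(frozen=True)
class VhgtCandidate:
    seq_id: str
    order: str
    host_clade_id: str
    host_majority: str
    majority_fraction: float


@dataclass(frozen=True)
class DisplacementCall:
    genome_id: str
    aars_class: str
    gene_context: str
    neighbor_majority: str


@dataclass
class RichnessProfile:
    per_genome: dict[str, frozenset[str]]
    clade_genomes: list[str]
    clade_total: int
    losses: list[str] = field(default_factory=list)


def detect_vhgt(clades: Sequence[ViralClade], ann: Mapping[str, TaxonAnnotation],
                majority_min: float = 0.7) -> list[VhgtCandidate]:
    """Minority tips within order-dominated (or rich-clade-dominated) clades.

    For each viral clade whose majority virus order reaches ``majority_min``,
    every tip of another order is a vHGT candidate with the majority order
    as the implied donor. Clades below the majority threshold are skipped as
    ambiguous. Within the dominant order, a tip whose aaRS-rich-clade flag
    contradicts the clade's dominant flag is also a candidate (rich-clade
    genes spreading to other Imitervirales, or vice versa).
    """
    out: list[VhgtCandidate] = []
    for clade in clades:
        if clade.n_viral < 2:
            continue
        orders = Counter(ann[m].group for m in clade.members)
        (top_order, top_n), = orders.most_common(1)
        frac = top_n / clade.n_viral
        if frac >= majority_min:
            for m in clade.members:
                if ann[m].group != top_order:
                    out.append(VhgtCandidate(
                        seq_id=m, order=ann[m].group,
                        host_clade_id=clade.clade_id,
                        host_majority=top_order, majority_fraction=frac))
        # rich-clade flag basis, within the dominant order
        same_order = [m for m in clade.members if ann[m].group == top_order]
        rich = Counter(ann[m].in_aars_rich_clade for m in same_order)
        (top_flag, flag_n), = rich.most_common(1)
        flag_frac = flag_n / len(same_order)
        if flag_frac >= majority_min and flag_frac < 1.0:
            label = f"{top_order}[rich]" if top_flag else f"{top_order}[non-rich]"
            for m in same_order:
                if ann[m].in_aars_rich_clade != top_flag:
                    out.append(VhgtCandidate(
                        seq_id=m, order=ann[m].group,
                        host_clade_id=clade.clade_id,
                        host_majority=label, majority_fraction=flag_frac))
    return out


def _nearest_tips(tree: PhyloTree, start: Node, wanted: set[str], k: int) -> list[str]:
    """k nearest tips (topological edge distance; ties lexicographic)."""
    dist: dict[int, int] = {id(start): 0}
    queue = deque([start])
    found: list[tuple[int, str]] = []
    while queue:
        node = queue.popleft()
        d = dist[id(node)]
        neighbours = list(node.children)
        if node.parent is not None:
            neighbours.append(node.parent)
        for nb in neighbours:
            if id(nb) in dist:
                continue
            dist[id(nb)] = d + 1
            if nb.is_leaf and nb.name in wanted and nb is not start:
                found.append((d + 1, nb.name))
            queue.append(nb)
    found.sort()
    return [name for _, name in found[:k]]


def detect_displacement(assignments: Mapping[str, str], species_tree: PhyloTree,
                        aars_class: str = "", k: int = 5) -> list[DisplacementCall]:
    """Genomes whose gene context contradicts their species-tree neighbours.

    ``assignments`` maps genome id -> gene-tree context label (one of
    ``GENE_CONTEXTS``). A genome is called displaced iff its own context
    differs from the strict-majority context of its ``k`` nearest labelled
    neighbours on the species tree AND that majority is ``main_viral`` (the
    relatives kept the vertically inherited gene; this genome's copy came
    from elsewhere).
    """
    tips = {l.name for l in species_tree.leaves()}
    for g, ctx in assignments.items():
        if g not in tips:
            raise KeyError(f"genome {g!r} not a species-tree tip")
        if ctx not in GENE_CONTEXTS:
            raise ValueError(f"unknown gene context {ctx!r} for {g}")
    labelled = set(assignments)
    out: list[DisplacementCall] = []
    for genome in sorted(assignments):
        start = species_tree.find_leaf(genome)
        neighbours = _nearest_tips(species_tree, start, labelled, k)
        if not neighbours:
            continue
        counts = Counter(assignments[n] for n in neighbours)
        (majority, n_maj), = counts.most_common(1)
        if 2 * n_maj <= len(neighbours):
            continue  # no strict majority among neighbours
        if majority == "main_viral" and assignments[genome] != majority:
            out.append(DisplacementCall(
                genome_id=genome, aars_class=aars_class,
                gene_context=assignments[genome], neighbor_majority=majority))
    return out


def richness_profile(calls: Sequence[AarsCall], species_tree: PhyloTree,
                     clade_leaves: Iterable[str],
                     loss_frac: float = 0.8) -> RichnessProfile:
    """aaRS class sets per genome plus totals and losses for a focal clade.

    The focal clade is the MRCA of ``clade_leaves``. ``clade_total`` counts
    the aaRS classes over the clade's genomes (with per-genome sets, i.e.
    one per class per genome). A class is reported as lost iff it is present
    in at least ``loss_frac`` of the clade's sister genomes but absent from
    every genome of the focal clade.
    """
    per_genome: dict[str, set[str]] = {}
    for c in calls:
        per_genome.setdefault(c.genome_id, set()).add(c.aars_class)
    tips = {l.name for l in species_tree.leaves()}
    clade_leaves = list(clade_leaves)
    missing = [g for g in clade_leaves if g not in tips]
    if missing:
        raise KeyError(f"genomes not on species tree: {missing}")
    if not clade_leaves:
        return RichnessProfile({g: frozenset(s) for g, s in per_genome.items()},
                               [], 0, [])
    node = species_tree.mrca(clade_leaves)
    clade_genomes = sorted(node.leaf_names())
    clade_total = sum(len(per_genome.get(g, ())) for g in clade_genomes)

    losses: list[str] = []
    if node.parent is not None:
        sisters = [s for s in node.parent.children if s is not node]
        sister_genomes = sorted({l.name for s in sisters for l in s.leaves()})
        if sister_genomes:
            focal_classes = set().union(*(per_genome.get(g, set())
                                          for g in clade_genomes)) if clade_genomes else set()
            all_classes = sorted({k for s in per_genome.values() for k in s})
            for klass in all_classes:
                have = sum(1 for g in sister_genomes if klass in per_genome.get(g, ()))
                if have / len(sister_genomes) >= loss_frac and klass not in focal_classes:
                    losses.append(klass)
    return RichnessProfile(
        per_genome={g: frozenset(s) for g, s in sorted(per_genome.items())},
        clade_genomes=clade_genomes,
        clade_total=clade_total,
        losses=losses,
    )


def vhgt_table(candidates: Sequence[VhgtCandidate]) -> str:
    lines = ["seq_id\torder\thost_clade\thost_majority\tmajority_fraction"]
    for c in candidates:
        lines.append(f"{c.seq_id}\t{c.order}\t{c.host_clade_id}\t"
                     f"{c.host_majority}\t{c.majority_fraction:.3f}")
    return "\n".join(lines) + "\n"


def displacement_table(calls: Sequence[DisplacementCall]) -> str:
    lines = ["genome_id\taars_class\tgene_context\tneighbor_majority"]
    for c in calls:
        lines.append(f"{c.genome_id}\t{c.aars_class}\t{c.gene_context}\t{c.neighbor_majority}")
    return "\n".join(lines) + "\n"
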