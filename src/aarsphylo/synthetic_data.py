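"""Synthetic annotated gene trees with planted evolutionary events.

The generator emulates the statistical structure the scenario classifier
assumes: a three-domain species scaffold (bacteria with organellar
lineages nested inside, archaea, eukaryote supergroups) plus virus orders
with an aaRS-rich subclade, onto which gene trees are realized by grafting
the viral clade according to a planted scenario. Support values are
simulated labels, not re-estimated — the package tests tree
interpretation, not tree inference. All randomness flows from explicit
seeds.

Also houses the packaged fixtures mirroring the published per-clade
scenario table and dataset-scale counts, used by the reporting layer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .clade_classifier import SCENARIOS, ScenarioCall
from .phylo_io import (TaxonAnnotation, annotation_map, write_annotations,
                       write_newick)
from .tree import Node, PhyloTree, SupportPair

SUPERGROUP_NAMES = (
    "Amorphea", "SAR", "Archaeplastida", "Excavata",
    "Haptista", "Cryptista", "CRuMs", "Hemimastigophora",
)
VIRUS_ORDER_NAMES = (
    "Imitervirales", "Algavirales", "Pimascovirales",
    "Asfuvirales", "Chitovirales", "Pandoravirales",
)


@dataclass
class ScaffoldConfig:
    """Taxon counts for the species scaffold.

    Defaults give a desk-scale caricature of the study's taxon sampling:
    several bacterial and archaeal phyla, four eukaryote supergroups deep
    enough that a LECA-wide clade is constructible, organellar lineages of
    bacterial (endosymbiotic) origin, and three virus orders with an
    aaRS-rich subclade inside the first.
    """

    bacteria_phyla: int = 6
    bacteria_per_phylum: int = 3
    archaea_phyla: int = 4
    archaea_per_phylum: int = 2
    euk_supergroups: int = 4
    taxa_per_supergroup: int = 6
    organellar_lineages: int = 2
    organellar_taxa: int = 3
    virus_orders: int = 3
    genomes_per_order: int = 5
    rich_subclade_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bacteria_phyla", "bacteria_per_phylum", "archaea_phyla",
                     "archaea_per_phylum", "euk_supergroups",
                     "taxa_per_supergroup", "organellar_lineages",
                     "organellar_taxa", "virus_orders", "genomes_per_order",
                     "rich_subclade_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.euk_supergroups < 3:
            raise ValueError("need >= 3 eukaryote supergroups for a LECA-wide clade")
        if self.euk_supergroups > len(SUPERGROUP_NAMES):
            raise ValueError(f"at most {len(SUPERGROUP_NAMES)} supergroups supported")
        if self.virus_orders > len(VIRUS_ORDER_NAMES):
            raise ValueError(f"at most {len(VIRUS_ORDER_NAMES)} virus orders supported")
        if self.rich_subclade_size > self.genomes_per_order:
            raise ValueError("rich subclade cannot exceed its order")


@dataclass
class ExtraEvent:
    """A planted within-virus event: ``loss``, ``displacement``, or ``vhgt``.

    ``target`` names the affected genome (loss/displacement) or the foreign
    genome inserted into the focal viral clade (vhgt).
    """

    kind: str
    target: str

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "displacement", "vhgt"):
            raise ValueError(f"unknown extra event {self.kind!r}")


@dataclass
class SimTruth:
    """Planted ground truth of one simulated gene tree."""

    scenario: str
    donor_group: str = ""
    recipient_group: str = ""
    depth_class: str = ""  # pre_leca | post_leca_deep | recent
    extra: list[ExtraEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.depth_class:
            self.depth_class = {
                "proto_euk_v": "pre_leca",
                "v_to_euk": "pre_leca",
                "ancient_euk_v": "post_leca_deep",
                "prok_v": "post_leca_deep",
                "recent_euk_to_v": "recent",
                "other_euk_v": "post_leca_deep",
            }[self.scenario]

    def to_json(self) -> str:
        return json.dumps({
            "scenario": self.scenario,
            "donor_group": self.donor_group,
            "recipient_group": self.recipient_group,
            "depth_class": self.depth_class,
            "extra": [{"kind": e.kind, "target": e.target} for e in self.extra],
        }, indent=1)


@dataclass
class NoiseModel:
    """Topological and support noise applied to a simulated gene tree.

    ``nni_prob`` is the per-edge probability of a random NNI applied to the
    edges around the planted viral attachment point; perturbed nodes (and
    deliberately unsupported plantings) get supports from the low ranges,
    everything else from the high ranges. Low-range maxima sit below the
    study thresholds so a low-support node never passes.
    """

    nni_prob: float = 0.0
    sh_high: tuple[float, float] = (85.0, 100.0)
    ufb_high: tuple[float, float] = (96.0, 100.0)
    tbe_high: tuple[float, float] = (80.0, 100.0)
    sh_low: tuple[float, float] = (20.0, 79.0)
    ufb_low: tuple[float, float] = (40.0, 94.0)
    tbe_low: tuple[float, float] = (10.0, 69.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sh_high", "ufb_high", "tbe_high", "sh_low", "ufb_low", "tbe_low"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"{name}=({lo}, {hi}) is not a range within [0, 100]")
        if not (0.0 <= self.nni_prob <= 1.0):
            raise ValueError("nni_prob must be a probability")


@dataclass
class Scaffold:
    """Species scaffold: tree plus per-tip annotations and handy groupings."""

    config: ScaffoldConfig
    tree: PhyloTree
    annotations: list[TaxonAnnotation]
    bacteria: list[str]
    archaea: list[str]
    nuclear: dict[str, list[str]]      # supergroup -> tips
    organellar: list[str]
    viral: dict[str, list[str]]        # order -> genome ids
    rich_clade: list[str]

    @property
    def ann(self) -> dict[str, TaxonAnnotation]:
        return annotation_map(self.annotations)

    def viral_species_tree(self) -> PhyloTree:
        genomes = [g for order in self.viral.values() for g in order]
        sub = PhyloTree(self.tree.mrca(genomes).copy(), rooted=True)
        sub.validate()
        return sub


def _balanced(names: Sequence[str], rng: np.random.Generator) -> Node:
    """Balanced binary subtree over leaf names, exponential branch lengths."""
    if len(names) == 1:
        return Node(name=names[0], length=float(rng.exponential(1.0)))
    mid = len(names) // 2
    node = Node(length=float(rng.exponential(1.0)))
    node.add_child(_balanced(names[:mid], rng))
    node.add_child(_balanced(names[mid:], rng))
    return node


def _join(children: Sequence[Node], rng: np.random.Generator) -> Node:
    """Left-ladder join of prebuilt subtrees."""
    node = children[0]
    for child in children[1:]:
        parent = Node(length=float(rng.exponential(1.0)))
        parent.add_child(node)
        parent.add_child(child)
        node = parent
    return node


def build_scaffold(cfg: Optional[ScaffoldConfig] = None) -> Scaffold:
    """Deterministic species scaffold for a given config.

    The root bipartition separates bacteria (with the organellar lineages
    nested inside, reflecting their endosymbiotic origin) from archaea plus
    eukaryotes; the virus orders form a separate subtree attached next to
    the eukaryote clade, with the aaRS-rich subclade flagged inside the
    first order.
    """
    cfg = cfg or ScaffoldConfig()
    rng = np.random.default_rng(cfg.seed)
    ann: list[TaxonAnnotation] = []

    bacteria: list[str] = []
    phylum_nodes: list[Node] = []
    for p in range(cfg.bacteria_phyla):
        names = [f"B{p+1}_{i+1}" for i in range(cfg.bacteria_per_phylum)]
        bacteria += names
        phylum_nodes.append(_balanced(names, rng))
        ann += [TaxonAnnotation(n, n, "bacteria", "not_applicable",
                                f"Bacteria-phylum-{p+1}") for n in names]
    organellar: list[str] = []
    for l in range(cfg.organellar_lineages):
        names = [f"O{l+1}_{i+1}" for i in range(cfg.organellar_taxa)]
        organellar += names
        phylum_nodes.append(_balanced(names, rng))
        ann += [TaxonAnnotation(
            n, n, "eukaryote", "organellar",
            SUPERGROUP_NAMES[i % cfg.euk_supergroups]) for i, n in enumerate(names)]
    bacteria_node = _join(phylum_nodes, rng)

    archaea: list[str] = []
    arch_nodes: list[Node] = []
    for p in range(cfg.archaea_phyla):
        names = [f"A{p+1}_{i+1}" for i in range(cfg.archaea_per_phylum)]
        archaea += names
        arch_nodes.append(_balanced(names, rng))
        ann += [TaxonAnnotation(n, n, "archaea", "not_applicable",
                                f"Archaea-phylum-{p+1}") for n in names]
    archaea_node = _join(arch_nodes, rng)

    nuclear: dict[str, list[str]] = {}
    sg_nodes: list[Node] = []
    for s in range(cfg.euk_supergroups):
        sg = SUPERGROUP_NAMES[s]
        names = [f"E_{sg}_{i+1}" for i in range(cfg.taxa_per_supergroup)]
        nuclear[sg] = names
        sg_nodes.append(_balanced(names, rng))
        ann += [TaxonAnnotation(n, n, "eukaryote", "nuclear", sg) for n in names]
    euk_node = _join(sg_nodes, rng)

    viral: dict[str, list[str]] = {}
    rich_clade: list[str] = []
    order_nodes: list[Node] = []
    for o in range(cfg.virus_orders):
        order = VIRUS_ORDER_NAMES[o]
        names = [f"V_{order}_{i+1}" for i in range(cfg.genomes_per_order)]
        viral[order] = names
        rich = set()
        if o == 0:
            rich = set(names[:cfg.rich_subclade_size])
            rich_clade = sorted(rich)
            parts = [_balanced(names[:cfg.rich_subclade_size], rng)]
            if len(names) > cfg.rich_subclade_size:
                parts.append(_balanced(names[cfg.rich_subclade_size:], rng))
            order_nodes.append(_join(parts, rng))
        else:
            order_nodes.append(_balanced(names, rng))
        for i, n in enumerate(names):
            ann.append(TaxonAnnotation(
                n, n, "virus", "not_applicable", order,
                source="isolate" if i == 0 else "mag",
                project="" if i == 0 else "tara",
                in_aars_rich_clade=n in rich))
    virus_node = _join(order_nodes, rng)

    root = Node()
    root.add_child(bacteria_node)
    right = Node(length=float(rng.exponential(1.0)))
    right.add_child(archaea_node)
    ev = Node(length=float(rng.exponential(1.0)))
    ev.add_child(euk_node)
    ev.add_child(virus_node)
    right.add_child(ev)
    root.add_child(right)

    tree = PhyloTree(root, rooted=True)
    _assign_supports(tree, NoiseModel(seed=cfg.seed), set())
    tree.validate()
    return Scaffold(cfg, tree, ann, bacteria, archaea, nuclear,
                    organellar, viral, rich_clade)


def _assign_supports(tree: PhyloTree, noise: NoiseModel, low_nodes: set[int],
                     rng: Optional[np.random.Generator] = None) -> None:
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    for node in tree.postorder():
        if node.is_leaf or node is tree.root:
            continue
        if id(node) in low_nodes:
            sh = rng.uniform(*noise.sh_low)
            ufb = rng.uniform(*noise.ufb_low)
            tbe = rng.uniform(*noise.tbe_low)
        else:
            sh = rng.uniform(*noise.sh_high)
            ufb = rng.uniform(*noise.ufb_high)
            tbe = rng.uniform(*noise.tbe_high)
        node.support = SupportPair(sh_alrt=round(sh, 1), ufb=round(ufb, 1),
                                   tbe=round(tbe, 1))


def _half_split(names: Sequence[str]) -> tuple[list[str], list[str]]:
    mid = (len(names) + 1) // 2
    return list(names[:mid]), list(names[mid:])


def simulate_gene_tree(scaffold: Scaffold, truth: SimTruth,
                       noise: Optional[NoiseModel] = None
                       ) -> tuple[PhyloTree, list[TaxonAnnotation], SimTruth]:
    """Realize a rooted gene tree with the planted scenario.

    The cellular backbone (bacteria + organellar lineages | archaea,
    eukaryote supergroups) is rebuilt from the scaffold taxa; the viral
    clade is grafted according to ``truth.scenario``:

    - ``proto_euk_v``     sister to the full eukaryote clade
    - ``ancient_euk_v``   sister to a two-supergroup eukaryote subclade
    - ``recent_euk_to_v`` inside one supergroup (sister to part of it)
    - ``v_to_euk``        a supergroup clade nested inside the viral clade,
                          viral tips on both flanks
    - ``prok_v``          sister to one bacterial phylum
    - ``other_euk_v``     as ancient, but the critical nodes get low support

    Extra loss/displacement/vhgt events prune or regraft tips. Node
    supports are drawn from the noise model; NNI noise hits the edges
    around the attachment point and marks them low-support.
    """
    noise = noise or NoiseModel()
    cfg = scaffold.config
    rng = np.random.default_rng(noise.seed)
    sgs = list(scaffold.nuclear)
    order0 = next(iter(scaffold.viral))
    viral_main = list(scaffold.viral[order0])

    extra = list(truth.extra)
    lost = {e.target for e in extra if e.kind == "loss"}
    displaced = {e.target for e in extra if e.kind == "displacement"}
    vhgt_in = [e.target for e in extra if e.kind == "vhgt"]
    viral_tips = [g for g in viral_main if g not in lost and g not in displaced]
    viral_tips += vhgt_in
    if truth.scenario == "v_to_euk":
        # both flanks need to outnumber the nested eukaryote clade
        for order, genomes in list(scaffold.viral.items())[1:]:
            viral_tips += [g for g in genomes if g not in viral_tips]
    if len(viral_tips) < 3:
        raise ValueError("viral clade too small for a plantable scenario")

    # cellular backbone
    phylum_nodes = [
        _balanced([f"B{p+1}_{i+1}" for i in range(cfg.bacteria_per_phylum)], rng)
        for p in range(cfg.bacteria_phyla)]
    org_nodes = [
        _balanced([f"O{l+1}_{i+1}" for i in range(cfg.organellar_taxa)], rng)
        for l in range(cfg.organellar_lineages)]
    arch_node = _join([
        _balanced([f"A{p+1}_{i+1}" for i in range(cfg.archaea_per_phylum)], rng)
        for p in range(cfg.archaea_phyla)], rng)
    sg_subtrees = {sg: _balanced(scaffold.nuclear[sg], rng) for sg in sgs}

    low_nodes: set[int] = set()
    viral_node = _balanced(sorted(viral_tips), rng)
    attach_parent: Node  # node whose children include the planted structure

    if truth.scenario == "prok_v":
        target_phylum = phylum_nodes[0]
        graft = Node(length=float(rng.exponential(1.0)))
        graft.add_child(viral_node)
        graft.add_child(target_phylum)
        phylum_nodes[0] = graft
        euk_node = _join([sg_subtrees[sg] for sg in sgs], rng)
        attach_parent = graft
    elif truth.scenario == "v_to_euk":
        nested_sg = sgs[0]
        flank_a, flank_b = _half_split(sorted(viral_tips))
        if len(flank_b) <= len(scaffold.nuclear[nested_sg]):
            raise ValueError(
                "v_to_euk needs viral flanks larger than the nested eukaryote "
                "clade; enlarge the viral sampling or shrink the supergroup")
        inner = Node(length=float(rng.exponential(1.0)))
        inner.add_child(_balanced(flank_b, rng))
        inner.add_child(sg_subtrees[nested_sg])
        outer = Node(length=float(rng.exponential(1.0)))
        outer.add_child(_balanced(flank_a, rng))
        outer.add_child(inner)
        rest = _join([sg_subtrees[sg] for sg in sgs[1:]], rng)
        euk_node = Node(length=float(rng.exponential(1.0)))
        euk_node.add_child(outer)
        euk_node.add_child(rest)
        attach_parent = outer
    elif truth.scenario == "recent_euk_to_v":
        target_sg = sgs[0]
        part_a, part_b = _half_split(scaffold.nuclear[target_sg])
        graft = Node(length=float(rng.exponential(1.0)))
        graft.add_child(viral_node)
        graft.add_child(_balanced(part_b, rng))
        sg_node = Node(length=float(rng.exponential(1.0)))
        sg_node.add_child(_balanced(part_a, rng))
        sg_node.add_child(graft)
        sg_subtrees[target_sg] = sg_node
        euk_node = _join([sg_subtrees[sg] for sg in sgs], rng)
        attach_parent = graft
    elif truth.scenario in ("ancient_euk_v", "other_euk_v"):
        pair = Node(length=float(rng.exponential(1.0)))
        pair.add_child(sg_subtrees[sgs[0]])
        pair.add_child(sg_subtrees[sgs[1]])
        graft = Node(length=float(rng.exponential(1.0)))
        graft.add_child(viral_node)
        graft.add_child(pair)
        rest = _join([sg_subtrees[sg] for sg in sgs[2:]], rng)
        euk_node = Node(length=float(rng.exponential(1.0)))
        euk_node.add_child(graft)
        euk_node.add_child(rest)
        attach_parent = graft
        if truth.scenario == "other_euk_v":
            low_nodes |= {id(viral_node), id(pair)}
    elif truth.scenario == "proto_euk_v":
        euks = _join([sg_subtrees[sg] for sg in sgs], rng)
        graft = Node(length=float(rng.exponential(1.0)))
        graft.add_child(viral_node)
        graft.add_child(euks)
        euk_node = graft
        attach_parent = graft
    else:  # pragma: no cover - SimTruth already validates
        raise ValueError(truth.scenario)

    # displaced genomes reappear embedded among eukaryotes of another supergroup
    for genome in sorted(displaced):
        host = sg_subtrees[sgs[-1]]
        tip = host.leaves()[0]
        kept = Node(name=tip.name, length=float(rng.exponential(1.0)))
        moved = Node(name=genome, length=float(rng.exponential(1.0)))
        tip.name = None  # the leaf becomes a cherry: (original, displaced virus)
        tip.add_child(kept)
        tip.add_child(moved)

    bact_node = _join(phylum_nodes + org_nodes, rng)
    root = Node()
    root.add_child(bact_node)
    right = Node(length=float(rng.exponential(1.0)))
    right.add_child(arch_node)
    right.add_child(euk_node)
    root.add_child(right)
    tree = PhyloTree(root, rooted=True)

    # NNI noise near the attachment point
    if noise.nni_prob > 0:
        candidates: list[Node] = []
        seen: set[int] = set()
        frontier = [attach_parent]
        for _ in range(3):
            nxt: list[Node] = []
            for node in frontier:
                for nb in ([node.parent] if node.parent else []) + node.children:
                    if id(nb) not in seen:
                        seen.add(id(nb))
                        nxt.append(nb)
            frontier = nxt
            candidates += [n for n in nxt
                           if not n.is_leaf and n.parent is not None
                           and n is not tree.root]
        for node in candidates:
            if rng.random() < noise.nni_prob:
                try:
                    tree.nni(node, swap_index=int(rng.integers(0, 4)))
                except ValueError:
                    continue
                low_nodes.add(id(node))
                if node.parent is not None:
                    low_nodes.add(id(node.parent))

    _assign_supports(tree, noise, low_nodes, rng)
    tree.validate()
    present = tree.leaf_names()
    ann = [a for a in scaffold.annotations if a.seq_id in present]
    return tree, ann, truth


def simulate_bootstrap_set(tree: PhyloTree, n_reps: int, perturb_prob: float,
                           seed: int = 0) -> list[PhyloTree]:
    """Bootstrap-like replicates: each internal edge independently NNI'd."""
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    if len(tree.leaves()) < 4:
        raise ValueError("need >= 4 leaves")
    rng = np.random.default_rng(seed)
    reps: list[PhyloTree] = []
    for _ in range(n_reps):
        rep = tree.copy()
        edges = [n for n in rep.postorder()
                 if not n.is_leaf and n.parent is not None]
        for node in edges:
            if rng.random() < perturb_prob:
                try:
                    rep.nni(node, swap_index=int(rng.integers(0, 4)))
                except ValueError:
                    continue
        reps.append(rep)
    return reps


# ---------------------------------------------------------------------------
# Packaged fixtures: the published per-clade scenario table and counts
# ---------------------------------------------------------------------------

#: One row per clade/branch of the published scenario table. Unnamed
#: clade cells and empty notes are blank. Scenario and support-basis
#: vocabulary matches the classifier's.
TABLE1_TSV = """\
aars\tclade\tscenario\tsupport_basis\tnotes
AlaRS\t\trecent_euk_to_v\ttopology_ufb_shalrt\t
CysRS\t\tancient_euk_v\ttopology_ufb_shalrt\t
AspRS\tClade I\tproto_euk_v\ttopology_ufb_shalrt\t
AspRS\tClade II\tother_euk_v\ttopology_ufb_shalrt\tTupanviruses and one MAG
GluRS\t\tproto_euk_v\ttopology_ufb_shalrt\t
PheRS\t\tproto_euk_v\ttopology_ufb_shalrt\tPutatively from organelles
GlyRS\tClade I\tproto_euk_v\ttopology_ufb_shalrt\t
GlyRS\tBranch I\tprok_v\ttopology_ufb_shalrt\tOrpheovirus
HisRS\tClade I\tother_euk_v\ttopology_ufb_shalrt\t
HisRS\tClade II\tv_to_euk\ttopology_only\t
HisRS\tClade III\tprok_v\ttopology_ufb_shalrt\t
IleRS\t\tproto_euk_v\ttopology_ufb_shalrt\t
LysRS\t\tproto_euk_v\ttopology_tbe\t
LeuRS\t\tproto_euk_v\ttopology_tbe\t
MetRS\tClade I\tancient_euk_v\ttopology_ufb_shalrt\t
MetRS\tClade II\tancient_euk_v\ttopology_ufb_shalrt\t
MetRS\t\trecent_euk_to_v\ttopology_only\tKlosneuvirus, hokovirus, and two MAGs
AsnRS\tClade I\tancient_euk_v\ttopology_ufb_shalrt\t
AsnRS\tClade II\tprok_v\ttopology_only\t
ProRS\tClade I\tother_euk_v\ttopology_only\t
ProRS\tClade II\tother_euk_v\ttopology_only\t
GlnRS\t\tother_euk_v\ttopology_only\t
ArgRS\tClade I\trecent_euk_to_v\ttopology_only\tOrpheovirus and one MAG
ArgRS\tClade II\tother_euk_v\ttopology_only\t
SerRS\tClade I\tother_euk_v\ttopology_ufb_shalrt\t
SerRS\tClade II\trecent_euk_to_v\ttopology_ufb_shalrt\tTupanviruses and one MAG
SerRS\tBranch I\trecent_euk_to_v\ttopology_ufb_shalrt\tOrpheovirus
ThrRS\tClade I\tancient_euk_v\ttopology_only\t
ThrRS\tClade II\trecent_euk_to_v\ttopology_only\tTupanviruses and one MAG
ValRS\tClade I\tprok_v\ttopology_ufb_shalrt\tTupanviruses
ValRS\tClade II\tprok_v\ttopology_only\t
TrpRS\tClade I\tother_euk_v\ttopology_ufb_shalrt\t
TrpRS\tClade II\tother_euk_v\ttopology_ufb_shalrt\t
TrpRS\tBranch I\trecent_euk_to_v\ttopology_ufb_shalrt\tPandoravirus salinus
TyrRS\tClade I\tv_to_euk\ttopology_ufb_shalrt\tEncompassing a eukaryotic clade
TyrRS\tClade II\tv_to_euk\ttopology_ufb_shalrt\tEncompassing a eukaryotic clade
"""

#: Dataset-scale counts as published; reproduced here as fixture arithmetic
#: only (the underlying genome data are external).
PAPER_COUNTS: dict[str, int] = {
    "input_mags": 4168,
    "nonredundant_mags": 3578,
    "reference_genomes": 224,
    "total_aars": 780,
    "genomes_with_aars": 273,
    "imitervirales_aars": 730,
    "asnrs_count": 144,
    "ilers_count": 125,
    "tyrrs_count": 84,
    "rich_clade_genomes": 64,
    "rich_clade_aars": 398,
    "eukaryote_species": 64,
    "bacteria_species": 142,
    "archaea_species": 76,
}


def load_table1_calls(text: Optional[str] = None) -> list[ScenarioCall]:
    """Parse the scenario-table fixture into :class:`ScenarioCall` rows."""
    lines = (text or TABLE1_TSV).splitlines()
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        out.append(ScenarioCall(
            aars_class=row["aars"], clade_id=row["clade"],
            scenario=row["scenario"], support_basis=row["support_basis"],
            notes=row.get("notes", "")))
    return out


def counts_report(counts: Optional[Mapping[str, int]] = None) -> dict[str, float]:
    """Headline shares recomputed from the counts fixture.

    Percentages follow the published rounding: the Imitervirales share to
    one decimal, per-class shares to whole percent.
    """
    c = dict(PAPER_COUNTS)
    if counts:
        c.update(counts)
    total = c["total_aars"]
    return {
        "imitervirales_share_pct": round(100.0 * c["imitervirales_aars"] / total, 1),
        "asnrs_share_pct": round(100.0 * c["asnrs_count"] / total),
        "ilers_share_pct": round(100.0 * c["ilers_count"] / total),
        "tyrrs_share_pct": round(100.0 * c["tyrrs_count"] / total),
        "rich_clade_share_of_order_pct": round(
            100.0 * c["rich_clade_aars"] / c["imitervirales_aars"], 1),
    }


def make_fixtures(outdir: str) -> dict[str, str]:
    """Write the packaged fixtures as plain-text files; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    t1 = os.path.join(outdir, "table1.tsv")
    with open(t1, "w") as fh:
        fh.write(TABLE1_TSV)
    paths["table1"] = t1
    counts = os.path.join(outdir, "counts.tsv")
    with open(counts, "w") as fh:
        fh.write("key\tvalue\n")
        for key, value in PAPER_COUNTS.items():
            fh.write(f"{key}\t{value}\n")
    paths["counts"] = counts
    return paths


def load_counts(path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                key, value = line.rstrip("\n").split("\t")
                out[key] = int(value)
    return out


def write_simulation(outdir: str, tree: PhyloTree,
                     ann: Sequence[TaxonAnnotation], truth: SimTruth) -> None:
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
        fh.write(write_newick(tree) + "\n")
    with open(os.path.join(outdir, "annotations.tsv"), "w") as fh:
        fh.write(write_annotations(ann))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json() + "\n")
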