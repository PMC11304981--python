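"""Six-way evolutionary-scenario classification of viral aaRS clades.

Given a rooted, annotated gene tree, this module extracts the maximal
clades made exclusively of nucleocytovirus tips, decides which are eligible
for interpretation (at least ``min_viral`` members, or containing an
isolate genome), and assigns each eligible clade one of six HGT scenarios:

- ``proto_euk_v``    ancient HGT between proto-eukaryotes and viruses
                     (viral clade sister to the LECA-wide eukaryote clade)
- ``ancient_euk_v``  ancient HGT predating the divergence of several major
                     eukaryote lineages, but not firmly pre-LECA
- ``recent_euk_to_v`` recent transfer from one eukaryote lineage to viruses
- ``v_to_euk``       transfer from viruses to eukaryotes (a eukaryote clade
                     nested inside viral context)
- ``other_euk_v``    eukaryote-virus exchange of unresolved timing
- ``prok_v``         exchange between prokaryotes and viruses

The rules are ordered (most topologically specific first) and exhaustive:
every eligible clade receives exactly one label. Rules 1-3 are structural
tests with the support basis recorded afterwards; the proto/ancient/other
split (rules 4-6) additionally conditions on whether the rule-critical
nodes pass the dual SH-aLRT/UFB thresholds, only the TBE threshold, or
neither.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .phylo_io import TaxonAnnotation
from .rooting_support import SupportThresholds, is_supported
from .tree import Node, PhyloTree

SCENARIOS = (
    "proto_euk_v", "ancient_euk_v", "recent_euk_to_v",
    "v_to_euk", "other_euk_v", "prok_v",
)

SUPPORT_BASES = ("topology_ufb_shalrt", "topology_tbe", "topology_only")


@dataclass
class ClassifierParams:
    """Knobs of the scenario classifier.

    ``leca_supergroups_min`` and ``leca_euk_fraction_min`` operationalize a
    "major eukaryotic clade" whose root corresponds to LECA: the sister
    eukaryote clade must span at least that many supergroups and hold at
    least that fraction of the tree's nuclear eukaryote tips.
    """

    min_viral: int = 3
    leca_supergroups_min: int = 3
    leca_euk_fraction_min: float = 0.5
    ancient_supergroups_min: int = 2
    prok_fraction_min: float = 0.8
    majority_viral_min: float = 0.5
    thresholds: SupportThresholds = field(default_factory=SupportThresholds)

    def __post_init__(self) -> None:
        if self.ancient_supergroups_min > self.leca_supergroups_min:
            raise ValueError("ancient_supergroups_min must be <= leca_supergroups_min")


@dataclass
class ViralClade:
    """A maximal clade whose tips are exclusively viral."""

    clade_id: str
    node: Node
    members: list[str]
    n_viral: int
    order_composition: dict[str, int]
    contains_isolate: bool
    eligible: bool


@dataclass
class SisterContext:
    """Composition of the viral clade's immediate sister and its eukaryote
    surroundings, reported as classification evidence."""

    domain_counts: dict[str, int]
    supergroups: frozenset[str]
    enclosing_euk_span: int
    enclosing_euk_fraction: float


@dataclass
class ScenarioCall:
    aars_class: str
    clade_id: str
    scenario: str
    support_basis: str
    notes: str = ""
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.support_basis not in SUPPORT_BASES:
            raise ValueError(f"unknown support basis {self.support_basis!r}")


class _Index:
    """Per-node tip composition, computed once per tree."""

    def __init__(self, tree: PhyloTree, ann: Mapping[str, TaxonAnnotation]) -> None:
        self.tree = tree
        self.ann = ann
        self.viral: dict[int, int] = {}
        self.bacteria: dict[int, int] = {}
        self.archaea: dict[int, int] = {}
        self.nuclear: dict[int, int] = {}
        self.organellar: dict[int, int] = {}
        self.total: dict[int, int] = {}
        self.nuc_groups: dict[int, frozenset[str]] = {}
        self.org_groups: dict[int, frozenset[str]] = {}
        for node in tree.postorder():
            if node.is_leaf:
                if node.name not in ann:
                    raise KeyError(f"tip {node.name!r} has no annotation")
                a = ann[node.name]
                self.viral[id(node)] = int(a.domain == "virus")
                self.bacteria[id(node)] = int(a.domain == "bacteria")
                self.archaea[id(node)] = int(a.domain == "archaea")
                self.nuclear[id(node)] = int(a.is_nuclear_eukaryote)
                self.organellar[id(node)] = int(a.is_organellar)
                self.total[id(node)] = 1
                self.nuc_groups[id(node)] = (
                    frozenset([a.group]) if a.is_nuclear_eukaryote else frozenset())
                self.org_groups[id(node)] = (
                    frozenset([a.group]) if a.is_organellar else frozenset())
            else:
                for table in (self.viral, self.bacteria, self.archaea,
                              self.nuclear, self.organellar, self.total):
                    table[id(node)] = sum(table[id(c)] for c in node.children)
                self.nuc_groups[id(node)] = frozenset().union(
                    *(self.nuc_groups[id(c)] for c in node.children))
                self.org_groups[id(node)] = frozenset().union(
                    *(self.org_groups[id(c)] for c in node.children))
        self.tree_nuclear = self.nuclear[id(tree.root)]

    def cellular(self, node: Node) -> int:
        return self.total[id(node)] - self.viral[id(node)]

    def prokaryote(self, node: Node) -> int:
        return self.bacteria[id(node)] + self.archaea[id(node)]

    def viral_frac(self, node: Node) -> float:
        return self.viral[id(node)] / self.total[id(node)]

    def all_viral(self, node: Node) -> bool:
        return self.viral[id(node)] == self.total[id(node)]

    def all_nuclear(self, node: Node) -> bool:
        return self.nuclear[id(node)] == self.total[id(node)]

    def all_organellar(self, node: Node) -> bool:
        return self.organellar[id(node)] == self.total[id(node)]

    def is_euk_clade(self, node: Node) -> bool:
        """Majority of the node's cellular tips are nuclear eukaryotes."""
        cell = self.cellular(node)
        return cell > 0 and self.nuclear[id(node)] / cell > 0.5


def extract_viral_clades(tree: PhyloTree, ann: Mapping[str, TaxonAnnotation],
                         params: Optional[ClassifierParams] = None) -> list[ViralClade]:
    """All maximal exclusively-viral clades, with eligibility flags.

    MAG singletons and pairs are returned but ineligible; any clade holding
    an isolate genome is eligible regardless of size (single-isolate
    branches are interpreted in their own right).
    """
    params = params or ClassifierParams()
    idx = _Index(tree, ann)
    clades: list[tuple[Node, list[str]]] = []
    for node in tree.postorder():
        if not idx.all_viral(node):
            continue
        if node.parent is None or not idx.all_viral(node.parent):
            members = sorted(node.leaf_names())
            clades.append((node, members))
    clades.sort(key=lambda item: item[1])
    out: list[ViralClade] = []
    for i, (node, members) in enumerate(clades, start=1):
        comp: dict[str, int] = {}
        has_isolate = False
        for m in members:
            a = ann[m]
            comp[a.group] = comp.get(a.group, 0) + 1
            if a.source == "isolate":
                has_isolate = True
        n = len(members)
        out.append(ViralClade(
            clade_id=f"VC{i:02d}",
            node=node,
            members=members,
            n_viral=n,
            order_composition=comp,
            contains_isolate=has_isolate,
            eligible=n >= params.min_viral or has_isolate,
        ))
    return out


def _max_nuclear_clades(tree: PhyloTree, idx: _Index) -> list[Node]:
    out = []
    for node in tree.postorder():
        if idx.all_nuclear(node) and (
                node.parent is None or not idx.all_nuclear(node.parent)):
            out.append(node)
    return out


def _is_descendant(node: Node, ancestor: Node) -> bool:
    if node is ancestor:
        return True
    return any(a is ancestor for a in node.ancestors())


def _support_basis(criticals: Sequence[Node], th: SupportThresholds) -> str:
    internal = [n for n in criticals if not n.is_leaf]
    if internal and all(is_supported(n, th, "ufb_shalrt") for n in internal):
        return "topology_ufb_shalrt"
    if internal and all(is_supported(n, th, "tbe") for n in internal):
        return "topology_tbe"
    return "topology_only"


def sister_context(tree: PhyloTree, clade: ViralClade,
                   ann: Mapping[str, TaxonAnnotation],
                   params: Optional[ClassifierParams] = None) -> SisterContext:
    """Composition of the clade's sister and its eukaryote surroundings."""
    params = params or ClassifierParams()
    idx = _Index(tree, ann)
    parent = clade.node.parent
    siblings = [c for c in parent.children if c is not clade.node] if parent else []
    domain_counts: dict[str, int] = {}
    groups: set[str] = set()
    for sib in siblings:
        for leaf in sib.leaves():
            a = ann[leaf.name]
            key = a.domain if a.domain != "eukaryote" else (
                "eukaryote_nuclear" if a.is_nuclear_eukaryote else "eukaryote_organellar")
            domain_counts[key] = domain_counts.get(key, 0) + 1
            if a.is_nuclear_eukaryote:
                groups.add(a.group)
    span, frac = 0, 0.0
    if parent is not None:
        enclosing = _smallest_enclosing_euk_clade(parent, idx, params.thresholds)
        if enclosing is not None:
            span = len(idx.nuc_groups[id(enclosing)])
            if idx.tree_nuclear:
                frac = idx.nuclear[id(enclosing)] / idx.tree_nuclear
    return SisterContext(domain_counts, frozenset(groups), span, frac)


def _smallest_enclosing_euk_clade(start: Node, idx: _Index,
                                  th: SupportThresholds) -> Optional[Node]:
    """Smallest ancestor-or-self that reads as a eukaryote clade, preferring
    supported nodes; None when no ancestor qualifies."""
    chain = [start, *start.ancestors()]
    candidates = [n for n in chain if idx.is_euk_clade(n)]
    for n in candidates:
        if is_supported(n, th, "ufb_shalrt") or is_supported(n, th, "tbe"):
            return n
    return candidates[0] if candidates else None


def classify_scenario(tree: PhyloTree, clade: ViralClade,
                      ann: Mapping[str, TaxonAnnotation],
                      params: Optional[ClassifierParams] = None,
                      aars_class: str = "") -> ScenarioCall:
    """Assign one of the six scenarios to an eligible viral clade.

    Ordered decision rules, first match wins; see the module docstring.
    """
    params = params or ClassifierParams()
    if not clade.eligible:
        raise ValueError(f"clade {clade.clade_id} is not eligible for classification")
    idx = _Index(tree, ann)
    th = params.thresholds
    c = clade.node
    parent = c.parent

    def call(scenario: str, criticals: Sequence[Node], notes: str = "",
             evidence: Optional[dict] = None) -> ScenarioCall:
        return ScenarioCall(
            aars_class=aars_class,
            clade_id=clade.clade_id,
            scenario=scenario,
            support_basis=_support_basis(criticals, th),
            notes=notes,
            evidence=evidence or {},
        )

    if parent is None:
        # a gene tree that is all-viral carries no cellular context at all
        return call("other_euk_v", [c], notes="no cellular context")

    # -- rule 1: prokaryotic neighbourhood ------------------------------
    # parent is the smallest clade properly containing c and >= 1 cellular
    # tip (c is maximal all-viral, so its parent cannot be all-viral).
    cell = idx.cellular(parent)
    prok_frac = idx.prokaryote(parent) / cell if cell else 0.0
    if prok_frac >= params.prok_fraction_min:
        return call("prok_v", [c, parent],
                    notes=f"{prok_frac:.0%} of neighbouring cellular tips prokaryotic",
                    evidence={"prok_fraction": prok_frac})

    # -- rule 2: eukaryote clade nested inside viral context ------------
    for e in _max_nuclear_clades(tree, idx):
        p = e.parent
        if p is None:
            continue
        if idx.viral_frac(p) <= params.majority_viral_min:
            continue
        enclosing = None
        for q in p.ancestors():
            if idx.viral_frac(q) > params.majority_viral_min:
                enclosing = q
                if is_supported(q, th, "ufb_shalrt") or is_supported(q, th, "tbe"):
                    break
            else:
                break  # viral context ends here
        if enclosing is not None and _is_descendant(c, enclosing):
            return call(
                "v_to_euk", [e, p, enclosing],
                notes="encompassing a eukaryotic clade",
                evidence={"nested_eukaryotes": sorted(e.leaf_names())})

    siblings = [s for s in parent.children if s is not c]
    sib_tips = [leaf for s in siblings for leaf in s.leaves()]
    sib_all_nuclear = bool(sib_tips) and all(
        ann[l.name].is_nuclear_eukaryote for l in sib_tips)
    sib_all_organellar = bool(sib_tips) and all(
        ann[l.name].is_organellar for l in sib_tips)
    sib_nuc_groups = {ann[l.name].group for l in sib_tips
                      if ann[l.name].is_nuclear_eukaryote}
    sib_org_groups = {ann[l.name].group for l in sib_tips
                      if ann[l.name].is_organellar}

    # -- rule 3: recent transfer below the eukaryote radiation ----------
    if sib_all_nuclear and len(sib_nuc_groups) <= 1:
        enclosing = fallback = None
        for a in parent.ancestors():
            if idx.is_euk_clade(a) and len(idx.nuc_groups[id(a)]) >= 2:
                if fallback is None:
                    fallback = a  # smallest qualifying, support aside
                if is_supported(a, th, "ufb_shalrt") or is_supported(a, th, "tbe"):
                    enclosing = a
                    break
        enclosing = enclosing or fallback
        if enclosing is not None:
            criticals = [c, *[s for s in siblings if not s.is_leaf], enclosing]
            return call(
                "recent_euk_to_v", criticals,
                notes=f"sister within {next(iter(sib_nuc_groups), '?')}",
                evidence={"sister": sorted(l.name for l in sib_tips)})

    # -- rules 4/5/6: sister-group depth x support ----------------------
    single_sister = siblings[0] if len(siblings) == 1 else None
    structure_span = 0
    leca_wide = False
    if single_sister is not None and sib_all_nuclear:
        structure_span = len(sib_nuc_groups)
        frac = (idx.nuclear[id(single_sister)] / idx.tree_nuclear
                if idx.tree_nuclear else 0.0)
        leca_wide = (structure_span >= params.leca_supergroups_min
                     and frac >= params.leca_euk_fraction_min)
    elif single_sister is not None and sib_all_organellar:
        structure_span = len(sib_org_groups)
        leca_wide = structure_span >= params.leca_supergroups_min

    if single_sister is not None and structure_span:
        criticals = [c, single_sister]
        basis = _support_basis(criticals, th)
        evidence = {
            "sister_span": structure_span,
            "leca_wide": leca_wide,
            "organellar_sister": sib_all_organellar,
        }
        if leca_wide and basis == "topology_ufb_shalrt":
            note = ("sister to organellar LECA-wide clade"
                    if sib_all_organellar else "sister to the major eukaryotic clade")
            return call("proto_euk_v", criticals, notes=note, evidence=evidence)
        if (structure_span >= params.ancient_supergroups_min
                and basis != "topology_only"):
            return call("ancient_euk_v", criticals,
                        notes=f"sister spans {structure_span} supergroups",
                        evidence=evidence)

    return call("other_euk_v", [c, *[s for s in siblings if not s.is_leaf]],
                notes="timing unresolved")


@dataclass
class ScenarioSummary:
    """Aggregate of a set of scenario calls, one call per clade/branch."""

    call_counts: dict[str, int]
    class_counts: dict[str, int]
    classes_by_scenario: dict[str, list[str]]
    pre_leca_classes: list[str]

    @property
    def n_pre_leca(self) -> int:
        return len(self.pre_leca_classes)


def summarize_scenarios(calls: Sequence[ScenarioCall]) -> ScenarioSummary:
    """Counts per scenario, distinct aaRS classes per scenario, and the
    pre-LECA tally.

    A class counts as pre-LECA if it has at least one ``proto_euk_v`` call,
    or if its only deep signal is a ``v_to_euk`` call noted as encompassing
    a eukaryotic clade (the nested pattern places the gene's origin at or
    before the proto-eukaryotic era regardless of transfer direction).
    """
    call_counts = {s: 0 for s in SCENARIOS}
    classes: dict[str, set[str]] = {s: set() for s in SCENARIOS}
    for c in calls:
        call_counts[c.scenario] += 1
        classes[c.scenario].add(c.aars_class)
    proto = classes["proto_euk_v"]
    encompassing = {
        c.aars_class for c in calls
        if c.scenario == "v_to_euk"
        and "encompassing a eukaryotic clade" in c.notes.lower()
        and c.aars_class not in proto
    }
    return ScenarioSummary(
        call_counts=call_counts,
        class_counts={s: len(classes[s]) for s in SCENARIOS},
        classes_by_scenario={s: sorted(classes[s]) for s in SCENARIOS},
        pre_leca_classes=sorted(proto | encompassing),
    )


def classify_all(tree: PhyloTree, ann: Mapping[str, TaxonAnnotation],
                 params: Optional[ClassifierParams] = None,
                 aars_class: str = "") -> list[ScenarioCall]:
    """Extract eligible clades and classify each; convenience wrapper."""
    params = params or ClassifierParams()
    return [
        classify_scenario(tree, clade, ann, params, aars_class=aars_class)
        for clade in extract_viral_clades(tree, ann, params)
        if clade.eligible
    ]


def subsection_tree(tree: PhyloTree, clade: ViralClade,
                    ann: Mapping[str, TaxonAnnotation],
                    params: Optional[ClassifierParams] = None,
                    radius: int = 2) -> PhyloTree:
    """Extract the clade plus its context for re-analysis on a subtree.

    Walks rootward from the clade until ``radius`` supported ancestors have
    been crossed (or the root is reached) and returns that subtree as a new
    rooted tree — the package's equivalent of building a subsection tree to
    sharpen a local topology.
    """
    params = params or ClassifierParams()
    th = params.thresholds
    node = clade.node
    crossed = 0
    for anc in clade.node.ancestors():
        node = anc
        if is_supported(anc, th, "ufb_shalrt") or is_supported(anc, th, "tbe"):
            crossed += 1
            if crossed >= radius:
                break
    sub = PhyloTree(node.copy(), rooted=True)
    sub.validate()
    return sub


def calls_table(calls: Sequence[ScenarioCall]) -> str:
    """Render calls as a TSV shaped like the published scenario table."""
    lines = ["aars\tclade\tscenario\tsupport_basis\tnotes"]
    for c in calls:
        lines.append(f"{c.aars_class}\t{c.clade_id}\t{c.scenario}\t"
                     f"{c.support_basis}\t{c.notes}")
    return "\n".join(lines) + "\n"
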