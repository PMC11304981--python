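"""Data-reduction rules upstream of tree interpretation.

ANI-based genome dereplication, gap-column trimming of protein alignments,
aaRS class assignment from tabular homology hits, and tree-based
contamination filtering of MAG-derived viral tips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .phylo_io import HitRecord, MSA, TaxonAnnotation
from .tree import PhyloTree

AARS_CLASSES = (
    "AlaRS", "ArgRS", "AsnRS", "AspRS", "CysRS", "GlnRS", "GluRS",
    "GlyRS", "HisRS", "IleRS", "LeuRS", "LysRS", "MetRS", "PheRS",
    "ProRS", "SerRS", "ThrRS", "TrpRS", "TyrRS", "ValRS",
)

#: Long-form enzyme names (as they appear in database descriptions) -> class.
DEFAULT_KEYWORD_MAP: dict[str, str] = {
    "alanyl-trna synthetase": "AlaRS",
    "arginyl-trna synthetase": "ArgRS",
    "asparaginyl-trna synthetase": "AsnRS",
    "aspartyl-trna synthetase": "AspRS",
    "cysteinyl-trna synthetase": "CysRS",
    "glutaminyl-trna synthetase": "GlnRS",
    "glutamyl-trna synthetase": "GluRS",
    "glycyl-trna synthetase": "GlyRS",
    "glycine--trna ligase": "GlyRS",
    "histidyl-trna synthetase": "HisRS",
    "isoleucyl-trna synthetase": "IleRS",
    "leucyl-trna synthetase": "LeuRS",
    "lysyl-trna synthetase": "LysRS",
    "methionyl-trna synthetase": "MetRS",
    "phenylalanyl-trna synthetase": "PheRS",
    "phenylalanine--trna ligase alpha": "PheRS",
    "prolyl-trna synthetase": "ProRS",
    "seryl-trna synthetase": "SerRS",
    "threonyl-trna synthetase": "ThrRS",
    "tryptophanyl-trna synthetase": "TrpRS",
    "tyrosyl-trna synthetase": "TyrRS",
    "valyl-trna synthetase": "ValRS",
}

#: Description substrings recorded as subtype notes when present.
SUBTYPE_NOTES = ("alpha", "glyrs-1", "lysrs-ii")


@dataclass(frozen=True)
class ANIRecord:
    """One pairwise average-nucleotide-identity comparison.

    ``coverage_smaller`` is the aligned fraction of the smaller genome, in
    percent.
    """

    genome_a: str
    genome_b: str
    ani: float
    coverage_smaller: float

    def __post_init__(self) -> None:
        if self.genome_a == self.genome_b:
            raise ValueError(f"self-comparison for {self.genome_a}")
        for nm in ("ani", "coverage_smaller"):
            v = getattr(self, nm)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{nm}={v} outside [0, 100]")


@dataclass(frozen=True)
class GenomeMeta:
    genome_id: str
    length_bp: int
    project: str = ""
    kind: str = "mag"  # mag | reference

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"nonpositive genome length for {self.genome_id}")
        if self.kind not in ("mag", "reference"):
            raise ValueError(f"unknown genome kind {self.kind!r}")


@dataclass(frozen=True)
class ContigMeta:
    contig_id: str
    genome_id: str
    has_core_gene: bool
    has_ncv_besthit_gene: bool


@dataclass(frozen=True)
class AarsCall:
    gene_id: str
    genome_id: str
    aars_class: str
    subtype_note: str = ""
    best_hit: Optional[HitRecord] = None

    def __post_init__(self) -> None:
        if self.aars_class not in AARS_CLASSES:
            raise ValueError(f"unknown aaRS class {self.aars_class!r}")


@dataclass
class DereplicationResult:
    """MAG clustering outcome: cluster membership and representatives.

    ``clusters`` maps representative genome id -> sorted member ids;
    reference genomes are passed through untouched in ``references``.
    """

    clusters: dict[str, list[str]]
    references: list[str]

    @property
    def representatives(self) -> list[str]:
        return sorted(self.clusters)


def dereplicate(ani: Sequence[ANIRecord], meta: Sequence[GenomeMeta],
                ani_min: float = 98.0, cov_min: float = 25.0) -> DereplicationResult:
    """Cluster MAGs by single-linkage on strict ANI/coverage edges.

    An edge joins a pair iff ani > ani_min AND coverage_smaller > cov_min
    (both strict). Clusters are connected components. The representative of
    a cluster is its largest genome from the Tara Oceans project, else its
    largest genome overall; ties break lexicographically by genome id.
    Reference genomes never participate in clustering.
    """
    by_id = {m.genome_id: m for m in meta}
    references = sorted(m.genome_id for m in meta if m.kind == "reference")
    mags = [m.genome_id for m in meta if m.kind == "mag"]

    parent: dict[str, str] = {g: g for g in mags}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for rec in ani:
        for g in (rec.genome_a, rec.genome_b):
            if g not in by_id:
                raise ValueError(f"genome {g!r} in ANI table but not in metadata")
        if by_id[rec.genome_a].kind != "mag" or by_id[rec.genome_b].kind != "mag":
            continue  # references kept outside MAG clustering
        if rec.ani > ani_min and rec.coverage_smaller > cov_min:
            union(rec.genome_a, rec.genome_b)

    groups: dict[str, list[str]] = {}
    for g in mags:
        groups.setdefault(find(g), []).append(g)

    def representative(members: list[str]) -> str:
        tara = [g for g in members if by_id[g].project == "tara"]
        pool = tara if tara else members
        return min(pool, key=lambda g: (-by_id[g].length_bp, g))

    clusters = {representative(members): sorted(members)
                for members in groups.values()}
    return DereplicationResult(clusters=clusters, references=references)


def trim_alignment(msa: MSA, max_gap_frac: float = 0.75) -> tuple[MSA, list[int]]:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_frac``.

    A column is kept iff gaps/rows <= max_gap_frac (strictly-more-gapped
    columns are removed). Returns the trimmed alignment and the kept column
    indices, 0-based ascending.
    """
    if len(msa) == 0:
        raise ValueError("empty alignment")
    n_rows = len(msa)
    kept: list[int] = []
    for col in range(msa.n_columns):
        gaps = sum(1 for row in msa.rows if row[col] == "-")
        if gaps / n_rows <= max_gap_frac:
            kept.append(col)
    rows = ["".join(row[c] for c in kept) for row in msa.rows]
    return MSA(ids=list(msa.ids), rows=rows), kept


def assign_aars(hits: Sequence[HitRecord], evalue_max: float = 1e-5,
                keyword_map: Optional[Mapping[str, str]] = None,
                gene_genome: Optional[Mapping[str, str]] = None) -> list[AarsCall]:
    """Call aaRS classes from homology hits: best hit per query only.

    The single best hit per query (highest bitscore; ties by lower E-value,
    then subject id) is examined; a call is emitted iff its E-value passes
    and its description matches an aaRS keyword. Queries whose best hit is
    not an aaRS yield no call, even if a lower-ranked hit is one.
    """
    kw = {k.lower(): v for k, v in (keyword_map or DEFAULT_KEYWORD_MAP).items()}
    best: dict[str, HitRecord] = {}
    order: list[str] = []
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            order.append(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (-cur.bitscore, cur.evalue, cur.subject_id):
            best[h.query_id] = h
    calls: list[AarsCall] = []
    for query in order:
        h = best[query]
        if h.evalue > evalue_max:
            continue
        desc = h.subject_description.lower()
        klass = next((kw[key] for key in kw if key in desc), None)
        if klass is None:
            continue
        note = next((s for s in SUBTYPE_NOTES if s in desc), "")
        genome = gene_genome[query] if gene_genome else query.split("|")[0]
        calls.append(AarsCall(gene_id=query, genome_id=genome,
                              aars_class=klass, subtype_note=note, best_hit=h))
    return calls


def flag_contamination(tree: PhyloTree, ann: Mapping[str, TaxonAnnotation],
                       contigs: Sequence[ContigMeta],
                       seq_contig: Optional[Mapping[str, str]] = None) -> set[str]:
    """Identify MAG-derived viral tips that are likely cellular contamination.

    A viral tip is flagged for removal iff (a) it does not sit inside any
    clade containing >= 2 viral tips, (b) it comes from a MAG, and (c) the
    contig encoding it carries neither a nucleocytovirus core gene nor any
    gene whose best hit is a nucleocytovirus. Isolate-derived tips are never
    flagged. A MAG tip without contig metadata is retained with a warning.
    """
    contig_by_id = {c.contig_id: c for c in contigs}
    contig_by_genome: dict[str, list[ContigMeta]] = {}
    for c in contigs:
        contig_by_genome.setdefault(c.genome_id, []).append(c)

    # lone viral tips = maximal all-viral clades of size 1
    lone: set[str] = set()
    viral_below: dict[int, int] = {}
    allviral: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            isv = ann[node.name].domain == "virus"
            viral_below[id(node)] = int(isv)
            allviral[id(node)] = isv
        else:
            viral_below[id(node)] = sum(viral_below[id(c)] for c in node.children)
            allviral[id(node)] = all(allviral[id(c)] for c in node.children)
    for leaf in tree.leaves():
        if ann[leaf.name].domain != "virus":
            continue
        # inside some clade with >= 2 viral tips, all-viral?
        in_multiviral = False
        node = leaf.parent
        while node is not None:
            if allviral[id(node)] and viral_below[id(node)] >= 2:
                in_multiviral = True
                break
            if not allviral[id(node)]:
                break
            node = node.parent
        if not in_multiviral:
            lone.add(leaf.name)

    flagged: set[str] = set()
    for seq_id in sorted(lone):
        a = ann[seq_id]
        if a.source != "mag":
            continue
        contig: Optional[ContigMeta] = None
        if seq_contig and seq_id in seq_contig:
            contig = contig_by_id.get(seq_contig[seq_id])
        elif a.genome_id in contig_by_genome and len(contig_by_genome[a.genome_id]) == 1:
            contig = contig_by_genome[a.genome_id][0]
        if contig is None:
            warnings.warn(f"no contig metadata for MAG tip {seq_id}; retained",
                          stacklevel=2)
            continue
        if not contig.has_core_gene and not contig.has_ncv_besthit_gene:
            flagged.add(seq_id)
    return flagged


def filter_tips(tree: PhyloTree, ann: Mapping[str, TaxonAnnotation],
                seq_lengths: Optional[Mapping[str, int]] = None,
                min_length_aa: int = 200,
                long_branch_factor: float = 5.0) -> set[str]:
    """Numeric stand-ins for manual removal of short / long-branch viral tips.

    Flags viral tips shorter than ``min_length_aa`` residues, and viral tips
    whose terminal branch exceeds ``long_branch_factor`` times the median
    terminal branch length of the tree. Requires branch lengths for the
    long-branch rule; without them only the length filter applies.
    """
    flagged: set[str] = set()
    if seq_lengths:
        for leaf in tree.leaves():
            if ann[leaf.name].domain == "virus" and \
                    seq_lengths.get(leaf.name, min_length_aa) < min_length_aa:
                flagged.add(leaf.name)
    tip_lengths = [l.length for l in tree.leaves() if l.length is not None]
    if tip_lengths:
        srt = sorted(tip_lengths)
        mid = len(srt) // 2
        median = srt[mid] if len(srt) % 2 else 0.5 * (srt[mid - 1] + srt[mid])
        if median > 0:
            for leaf in tree.leaves():
                if leaf.length is not None and ann[leaf.name].domain == "virus" \
                        and leaf.length > long_branch_factor * median:
                    flagged.add(leaf.name)
    return flagged
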