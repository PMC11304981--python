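"""Readers and writers for the formats the pipeline touches.

Newick trees with IQ-TREE-style dual support labels ("SH-aLRT/UFB" on
internal nodes), taxon annotation TSVs, aligned protein FASTA, and tabular
homology-search hit files. Newick grammar handling is delegated to dendropy;
this module owns the interpretation of support labels and the conversion to
the package's :class:`~aarsphylo.tree.PhyloTree`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .tree import Node, PhyloTree, SupportPair

DOMAINS = frozenset({"virus", "bacteria", "archaea", "eukaryote"})
COMPARTMENTS = frozenset({"nuclear", "organellar", "not_applicable"})
SOURCES = frozenset({"isolate", "mag"})

ANNOTATION_COLUMNS = (
    "seq_id", "genome_id", "domain", "compartment", "group",
    "subgroup", "source", "project", "in_aars_rich_clade",
)


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending spot."""


@dataclass(frozen=True)
class TaxonAnnotation:
    """Per-sequence labels tying a tree tip to its organism and provenance."""

    seq_id: str
    genome_id: str
    domain: str
    compartment: str
    group: str
    subgroup: str = ""
    source: str = "isolate"
    project: str = ""
    in_aars_rich_clade: bool = False

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ParseError(f"unknown domain {self.domain!r} for {self.seq_id}")
        if self.compartment not in COMPARTMENTS:
            raise ParseError(
                f"unknown compartment {self.compartment!r} for {self.seq_id}")
        if self.source not in SOURCES:
            raise ParseError(f"unknown source {self.source!r} for {self.seq_id}")
        if self.domain == "virus" and self.compartment != "not_applicable":
            raise ParseError(
                f"viral sequence {self.seq_id} must have compartment=not_applicable")

    @property
    def is_nuclear_eukaryote(self) -> bool:
        return self.domain == "eukaryote" and self.compartment == "nuclear"

    @property
    def is_organellar(self) -> bool:
        return self.domain == "eukaryote" and self.compartment == "organellar"

    @property
    def is_prokaryote(self) -> bool:
        return self.domain in ("bacteria", "archaea")


@dataclass
class MSA:
    """An aligned set of protein sequences (rows equal length, ids unique)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ParseError("MSA ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ParseError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ParseError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    subject_description: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ParseError(f"negative E-value for {self.query_id}")


_SUPPORT_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")
_NUMBER_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*$")


def _label_to_support(label: Optional[str], swap: bool = False) -> Optional[SupportPair]:
    """Interpret an internal-node label as support.

    "X/Y" -> SH-aLRT X, UFB Y (order per IQ-TREE's ``--alrt ... -B ...``;
    ``swap=True`` for producers that print UFB first). A single number is
    UFB only. Anything else is not a support label.
    """
    if not label:
        return None
    m = _SUPPORT_RE.match(label)
    if m:
        a, b = float(m.group(1)), float(m.group(2))
        if swap:
            a, b = b, a
        return SupportPair(sh_alrt=a, ufb=b, raw=label.strip())
    m = _NUMBER_RE.match(label)
    if m:
        return SupportPair(ufb=float(m.group(1)), raw=label.strip())
    return None


def parse_newick(text: str, swap_support: bool = False, rooted: bool = True) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Internal labels of the form ``X/Y`` become (SH-aLRT, UFB) support pairs;
    a bare number becomes UFB. Absent labels are *missing* support, never 0.
    """
    if not text or not text.strip():
        raise ParseError("empty Newick input")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise ParseError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types w/ positions
        raise ParseError(f"Newick parse error: {exc}") from None

    def convert(dnode: dendropy.Node) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(name=name, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            node.support = _label_to_support(dnode.label, swap=swap_support)
            if node.support is None and dnode.label:
                node.name = dnode.label  # a genuine internal name
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)

    def collapse_unary(node: Node) -> Node:
        # tolerate unary internal nodes on input; merge their edges
        node.children = [collapse_unary(c) for c in node.children]
        for c in node.children:
            c.parent = node
        if len(node.children) == 1 and node is not root:
            (only,) = node.children
            if node.length is not None or only.length is not None:
                only.length = (node.length or 0.0) + (only.length or 0.0)
            return only
        return node

    root = collapse_unary(root)
    while len(root.children) == 1 and not root.children[0].is_leaf:
        root = root.children[0]
        root.parent = None
        root.length = None
    tree = PhyloTree(root, rooted=rooted)
    tree.validate()
    return tree


def parse_newick_set(text: str, **kwargs) -> list[PhyloTree]:
    """Parse a multi-Newick file: one tree per ';'-terminated statement."""
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";", **kwargs))
    if not trees:
        raise ParseError("no trees found in multi-Newick input")
    return trees


def _fmt_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def _node_label(node: Node) -> str:
    if node.support is not None:
        sp = node.support
        if sp.raw is not None:
            return sp.raw
        parts = []
        if sp.sh_alrt is not None and sp.ufb is not None:
            return f"{_fmt_length(sp.sh_alrt)}/{_fmt_length(sp.ufb)}"
        if sp.ufb is not None:
            return _fmt_length(sp.ufb)
        if sp.sh_alrt is not None:
            return f"{_fmt_length(sp.sh_alrt)}/"
    return node.name or ""


def _needs_quotes(name: str) -> bool:
    return bool(re.search(r"[\s()\[\]{}:;,']", name))


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; support labels round-trip as their decimal strings."""

    def render(node: Node) -> str:
        if node.is_leaf:
            name = node.name or ""
            if _needs_quotes(name):
                name = "'" + name.replace("'", "''") + "'"
            out = name
        else:
            inner = ",".join(render(c) for c in node.children)
            out = f"({inner}){_node_label(node)}"
        if node.length is not None:
            out += f":{_fmt_length(node.length)}"
        return out

    return render(tree.root) + ";"


def write_newick_set(trees: Sequence[PhyloTree]) -> str:
    return "\n".join(write_newick(t) for t in trees) + "\n"


def _split_tsv(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        if line.strip() and not line.startswith("#"):
            rows.append(line.rstrip("\n").split("\t"))
    return rows


def parse_annotations(text: str) -> list[TaxonAnnotation]:
    """Parse the taxon annotation TSV (header required, one row per seq_id)."""
    rows = _split_tsv(text)
    if not rows:
        raise ParseError("empty annotation table")
    header = rows[0]
    missing = [c for c in ANNOTATION_COLUMNS if c not in header]
    if missing:
        raise ParseError(f"annotation table missing columns: {missing}")
    idx = {c: header.index(c) for c in ANNOTATION_COLUMNS}
    out: list[TaxonAnnotation] = []
    errors: list[str] = []
    seen: dict[str, int] = {}
    for ln, row in enumerate(rows[1:], start=2):
        if len(row) < len(header):
            errors.append(f"line {ln}: expected {len(header)} columns, got {len(row)}")
            continue
        seq_id = row[idx["seq_id"]]
        if seq_id in seen:
            errors.append(f"line {ln}: duplicate seq_id {seq_id!r} (first at line {seen[seq_id]})")
            continue
        seen[seq_id] = ln
        try:
            out.append(TaxonAnnotation(
                seq_id=seq_id,
                genome_id=row[idx["genome_id"]],
                domain=row[idx["domain"]],
                compartment=row[idx["compartment"]],
                group=row[idx["group"]],
                subgroup=row[idx["subgroup"]],
                source=row[idx["source"]],
                project=row[idx["project"]],
                in_aars_rich_clade=row[idx["in_aars_rich_clade"]].strip() in ("1", "true", "True"),
            ))
        except ParseError as exc:
            errors.append(f"line {ln}: {exc}")
    if errors:
        raise ParseError("annotation table errors:\n" + "\n".join(errors))
    return out


def write_annotations(annotations: Iterable[TaxonAnnotation]) -> str:
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for a in annotations:
        lines.append("\t".join([
            a.seq_id, a.genome_id, a.domain, a.compartment, a.group,
            a.subgroup, a.source, a.project, "1" if a.in_aars_rich_clade else "0",
        ]))
    return "\n".join(lines) + "\n"


def annotation_map(annotations: Iterable[TaxonAnnotation]) -> dict[str, TaxonAnnotation]:
    out: dict[str, TaxonAnnotation] = {}
    for a in annotations:
        if a.seq_id in out:
            raise ParseError(f"duplicate annotation for {a.seq_id}")
        out[a.seq_id] = a
    return out


def parse_alignment(text: str) -> MSA:
    """Parse aligned FASTA (protein + gap '-')."""
    ids: list[str] = []
    rows: list[str] = []
    current: Optional[list[str]] = None
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current is not None:
                rows.append("".join(current))
            ids.append(line[1:].split()[0])
            current = []
        else:
            if current is None:
                raise ParseError(f"line {ln}: sequence data before first header")
            current.append(line)
    if current is not None:
        rows.append("".join(current))
    if not ids:
        raise ParseError("no FASTA records found")
    return MSA(ids=ids, rows=rows)


def write_alignment(msa: MSA) -> str:
    return "".join(f">{i}\n{r}\n" for i, r in zip(msa.ids, msa.rows))


DEFAULT_HIT_COLUMNS = {
    "query_id": 0,
    "subject_id": 1,
    "evalue": 10,
    "bitscore": 11,
    "subject_description": 12,
}


def parse_hits(text: str, columns: Optional[Mapping[str, int]] = None) -> list[HitRecord]:
    """Parse 12(+)-column tabular homology hits; stable sort by query then
    descending bitscore (tie: ascending E-value, then subject id)."""
    cols = dict(DEFAULT_HIT_COLUMNS)
    if columns:
        cols.update(columns)
    hits: list[HitRecord] = []
    for ln, row in enumerate(_split_tsv(text), start=1):
        try:
            evalue = float(row[cols["evalue"]])
            bitscore = float(row[cols["bitscore"]])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"hit table line {ln}: {exc}") from None
        desc_idx = cols["subject_description"]
        desc = row[desc_idx] if desc_idx < len(row) else ""
        hits.append(HitRecord(
            query_id=row[cols["query_id"]],
            subject_id=row[cols["subject_id"]],
            evalue=evalue,
            bitscore=bitscore,
            subject_description=desc,
        ))
    hits.sort(key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id))
    return hits
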