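# Methods

## Problem and scope

The package interprets already-inferred gene trees of aminoacyl-tRNA
synthetases (aaRSs) shared by nucleocytoviruses and cellular organisms. It
does not align sequences, search models, or estimate trees: alignment,
ML inference, SH-aLRT/UFB estimation, AU-test p-values, DIAMOND searches
and ANI computation are upstream/downstream tools whose outputs (aligned
FASTA, Newick with dual support labels, tabular hits, ANI tables) this
package consumes or prepares inputs for. What it owns is the
tree-interpretation layer: rooting, clade eligibility, scenario
classification, TBE, constraint enumeration, intra-viral event detection,
and the synthetic benchmark that validates them.

## Rooting at the prokaryote split

aaRS trees are rooted on the branch separating the major bacterial and
archaeal clades (a rooting justified by anciently duplicated paralogs).
Operationally, every edge is scored as
`max over orientation of (fraction of bacterial tips on one side) ×
(fraction of archaeal tips on the other)`; non-prokaryote tips are
ignored. The root goes on the maximal edge; ties prefer the edge most
balanced in prokaryote tip count, then the lexicographically smallest
below-side leaf set, which makes the choice deterministic and independent
of tip order.

A geometric note: when bacteria and archaea are each monophyletic, score 1
is attained on *every* edge of the path between the two clades (other taxa
hang off that path), not on a single edge. The rooting property we test is
therefore "the chosen edge perfectly separates the two domains", with the
tie-break fixing which path edge is used. The split position on the chosen
edge (midpoint) is presentation only.

## Support

A node is statistically supported on the dual basis iff SH-aLRT ≥ 80 and
UFB ≥ 95, or on the TBE basis iff TBE ≥ 70 (percent). Thresholds are
inclusive by default — figure-legend wording — with a strict (>) mode for
producers that treat them as exclusive; the worked boundary case
(UFB 94 / SH-aLRT 96.8) fails under both readings. Missing support values
never pass: an unlabeled node is unknown, not zero.

TBE is computed by exhaustive transfer-distance comparison:
`TBE(b) = 100·(1 − mean_T [min_{b′∈T} δ(b,b′)] / (p−1))` where p is the
lighter-side size of the reference branch and δ the symmetric-difference
distance under the better orientation, minimized over all branches of each
bootstrap tree including trivial (leaf) branches — which caps δ at p−1.
This is the O(branches² · leaves) brute force, adequate at desk scale; the
O(n log n) algorithm is out of scope. For cherries (p = 2) the formula
reduces to the classical Felsenstein proportion, and TBE ≥ Felsenstein on
every branch — both are regression-tested against an independent oracle.

## Viral clades and the six scenarios

Viral clades are the maximal clades whose tips are exclusively viral.
A clade is eligible for interpretation iff it has ≥ 3 viral members or
contains an isolate genome; MAG singletons and pairs are set aside as
likely contamination (the decontamination rule removes a lone MAG tip only
when its contig carries neither a core gene nor any gene with a
nucleocytovirus best hit; isolate tips are never removed).

Classification applies six ordered rules, first match wins, so the labels
are mutually exclusive and exhaustive:

1. **prok_v** — the smallest clade properly containing the viral clade has
   ≥ 80% prokaryotic cellular tips (the 80% is a declared default; the
   source analyses reasoned qualitatively).
2. **v_to_euk** — some nuclear-eukaryote clade is nested in viral context:
   its parent is majority-viral (> 50% of tips, configurable) and at least
   one further enclosing node is majority-viral, with the focal viral
   clade inside that region.
3. **recent_euk_to_v** — the viral clade's sister is nuclear-eukaryotic
   spanning ≤ 1 supergroup, while the smallest enclosing eukaryote clade
   spans ≥ 2 supergroups: the transfer postdates the eukaryote radiation.
4. **proto_euk_v** — the viral clade and its eukaryote sister are both
   supported on the dual basis, and the sister is LECA-wide: ≥ 3
   supergroups and ≥ 50% of the tree's nuclear tips (both knobs in
   `ClassifierParams`). An organellar variant accepts a supported
   all-organellar sister spanning ≥ 3 supergroups (the mitochondrial-like
   pattern).
5. **ancient_euk_v** — the rule-4 structure with the sister spanning ≥ 2
   supergroups but short of LECA-wide, or the full rule-4 structure whose
   critical nodes pass only the TBE threshold.
6. **other_euk_v** — eukaryotic sister context not matching any of the
   above (including structurally proto/ancient patterns with unsupported
   critical nodes): timing unresolved.

Rules 1–3 are structural; the recorded `support_basis`
(`topology_ufb_shalrt` / `topology_tbe` / `topology_only`) reflects
whether every rule-critical node passes the dual thresholds, only TBE, or
neither. Support enters the firing condition only at the proto/ancient/
other boundary — that split is one consistent operationalization of a
judgment the source analyses made per tree, and the per-clade JSON
evidence is emitted so a curator can revisit it. Organellar tips never
count toward nuclear-tip fractions.

The rule order (prok → nested → recent → proto → ancient → other) puts the
most topologically specific patterns first. Subsection re-analysis is
supported by extracting the clade plus its context out to a configurable
number of supported ancestors (default 2) and re-running classification.

Aggregation counts calls per scenario and distinct aaRS classes per
scenario. The pre-LECA tally counts classes with ≥ 1 `proto_euk_v` call
plus classes whose only deep signal is a `v_to_euk` call noted as
encompassing a eukaryotic clade — under the nested pattern the gene is at
least as old as the transfer regardless of direction.

## Constrained topologies

For AU testing of the proto-eukaryotic scenario, the major eukaryote clade
is split into three subclades at its top two bipartitions; a bipartition
shaving off one or two tips is skipped and those tips are excluded. Which
side is split second is genuinely open; we split the larger side
(configurable). All rooted binary arrangements of {E1, E2, E3, V} are then
enumerated — (2·4−3)!! = 15, generated recursively and deduplicated by
canonical clade sets — of which exactly 3 keep {E1, E2, E3} monophyletic
("original") and 12 place V inside ("alternative"). Constraints are
written as Newick with groups as multifurcations plus a manifest TSV; the
AU test itself runs externally.

## Intra-viral events

- **vHGT**: inside each viral clade whose dominant virus order (or, within
  the dominant order, whose aaRS-rich-clade flag) reaches the majority
  threshold (default 0.7), every contradicting tip is a candidate with the
  majority group as implied donor; clades below the threshold are skipped
  as ambiguous. The rich-clade membership is an input flag (it is defined
  on the core-gene species tree, which this package consumes, not builds).
- **Displacement**: a genome whose gene-tree context (e.g.
  `eukaryote_embedded`) differs from the strict-majority context of its
  k = 5 nearest species-tree neighbours, when that majority is
  `main_viral`.
- **Richness/loss**: per-genome aaRS class sets; a class is a candidate
  loss in a focal clade when ≥ 80% of the sister genomes carry it and no
  focal genome does. k and the 80% are declared defaults.

## Synthetic data

The scaffold is a deterministic species tree: bacteria phyla (with
organellar lineages nested inside, reflecting endosymbiotic origin),
archaea phyla, ≥ 3 eukaryote supergroups, and virus orders with a flagged
aaRS-rich subclade — by default 6×3 bacteria, 4×2 archaea, 4×6 nuclear
eukaryotes, 2×3 organellar tips and 3×5 viral genomes, a desk-scale
caricature of the study's taxon sampling chosen so that every scenario's
defining pattern is geometrically realizable (e.g. the nested v_to_euk
pattern needs viral flanks larger than the nested supergroup). Gene trees
are rebuilt from the scaffold taxa with the viral clade grafted per
scenario; `other_euk_v` is planted as the ancient structure with
deliberately low support on the critical nodes, mirroring the
topology-only rows of the published table.

Supports are simulated labels (high ranges pass both thresholds, low
ranges pass neither), not re-estimated — the package tests tree
interpretation, not inference, so passing recovery tests says nothing
about alignment or ML-search error on real data. Branch lengths are
exponential(1) cosmetics; nothing downstream reads them. NNI noise is
applied near the planted attachment point (where it can actually disturb
the diagnostic topology) and marks perturbed nodes low-support; recall
degrades smoothly as the NNI probability rises. Bootstrap sets for TBE are
per-edge NNI perturbations of the reference tree. All randomness flows
from explicit integer seeds; identical inputs give byte-identical Newick.

The packaged fixtures transcribe the published per-clade scenario table
(36 rows; unnamed clade cells blank) and dataset-scale counts (780 aaRSs
in 273 genomes, 730 in *Imitervirales*, the 64-genome rich clade with 398
aaRSs, etc.). Those totals depend on external MAG data and are reproduced
only as fixture arithmetic, never re-derived from synthetic trees.

## Numerical and degenerate-input choices

- Strict inequalities in dereplication (ANI > 98, coverage > 25) and
  trimming ("more than" the gap fraction is removed, so a column exactly
  at the threshold is kept); single-linkage connected components for
  clustering, the minimal reading of pairs being "clustered together";
  representative = largest Tara genome, ties lexicographic.
- "Short" and "long-branch" removal of putative nonfunctional genes has no
  published numbers; exposed as explicit filters (min 200 aa; terminal
  branch > 5× the median terminal branch), both configurable.
- Reference genomes are excluded from ANI clustering (unstated upstream;
  declared here).
- Polytomies are accepted and preserved everywhere; monophyly and
  bipartition logic work on multifurcations without resolving them.
  Unary Newick nodes are collapsed on input. Absent support labels are
  missing, never 0.
- Problem sizes in the test suite (scaffolds of ~60 tips, 200+ recovery
  simulations, 8–16-leaf TBE oracles, 100 rooting scaffolds) are the
  package's own benchmark choices: large enough to exercise every rule,
  small enough to run interactively.

## Known limitations

- The classifier encodes one consistent reading of narrative per-tree
  judgments; the ancient/other boundary in particular is a convention, and
  topology-only rows can land differently than expert curation.
- vHGT direction is a hint (majority = donor); the alternative
  "ancestral acquisition with subsequent losses" cannot be distinguished
  from topology alone and is not claimed.
- The generator does not simulate sequences, rate heterogeneity,
  long-branch attraction, or coalescent/duplication processes — the very
  artifacts that motivate TBE and subsection trees on real data — so
  recovery rates here are upper bounds on real-data performance.
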