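"""Enumerate the 15 constrained topologies used for AU testing.

Splits a simulated major eukaryote clade into three subclades at its top
two bipartitions and enumerates every rooted binary arrangement of
{E1, E2, E3, V}: 3 "original" topologies keep the eukaryote group
monophyletic with the viral clade outside; 12 "alternative" topologies
place the viral clade within the eukaryote group.
"""

from aarsphylo import (NoiseModel, SimTruth, annotation_map, build_scaffold,
                       enumerate_constraints, simulate_gene_tree,
                       split_top_bipartitions)

scaffold = build_scaffold()
tree, annotations, _ = simulate_gene_tree(
    scaffold, SimTruth("proto_euk_v"), NoiseModel(seed=3))
ann = annotation_map(annotations)

euks = [n for n in tree.leaf_names() if ann[n].is_nuclear_eukaryote]
virals = [n for n in tree.leaf_names() if ann[n].domain == "virus"]

partition = split_top_bipartitions(tree.mrca(euks))
print("subclade sizes  :", len(partition.e1), len(partition.e2),
      len(partition.e3), "  excluded:", len(partition.excluded))

topologies = enumerate_constraints(partition, virals)
print("topologies      :", len(topologies))
print("original        :", sum(t.klass == "original" for t in topologies))
print("alternative     :", sum(t.klass == "alternative" for t in topologies))
print("example newick  :", topologies[0].newick[:70], "...")

# Each topology is a Newick constraint (groups as multifurcations) ready
# for an external AU-test runner; rejecting all 12 alternatives would pin
# the viral clade outside the eukaryote radiation.
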