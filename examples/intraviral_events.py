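"""Detect within-virus events: vHGT, displacement, and gene loss.

Plants a virus-to-virus HGT, a displacement, and a loss in a simulated
gene tree, then runs the three intra-viral detectors.
"""

from aarsphylo import (NoiseModel, SimTruth, annotation_map, build_scaffold,
                       detect_displacement, detect_vhgt, extract_viral_clades,
                       richness_profile, simulate_gene_tree)
from aarsphylo.preprocess import AarsCall
from aarsphylo.synthetic_data import ExtraEvent

scaffold = build_scaffold()
alien = scaffold.viral["Algavirales"][1]       # vHGT donor-side tip
lost = scaffold.viral["Imitervirales"][3]      # loses the gene
tree, annotations, truth = simulate_gene_tree(
    scaffold,
    SimTruth("proto_euk_v", extra=[ExtraEvent("vhgt", alien),
                                   ExtraEvent("loss", lost)]),
    NoiseModel(seed=5))
ann = annotation_map(annotations)

# 1. vHGT: a minority-order tip inside an order-dominated clade
clades = extract_viral_clades(tree, ann)
for cand in detect_vhgt(clades, ann):
    print(f"vHGT candidate  : {cand.seq_id} ({cand.order}) inside a clade "
          f"{cand.majority_fraction:.0%} {cand.host_majority}")

# 2. displacement: gene context contradicts the species-tree neighbourhood
species_tree = scaffold.viral_species_tree()
contexts = {g: "main_viral" for order in scaffold.viral.values() for g in order}
contexts["V_Imitervirales_2"] = "eukaryote_embedded"   # observed in the gene tree
for call in detect_displacement(contexts, species_tree, aars_class="AspRS"):
    print(f"displacement    : {call.genome_id} is {call.gene_context} while "
          f"its relatives are {call.neighbor_majority}")

# 3. richness + loss: the rich subclade vs its sister genomes
calls = [AarsCall(f"{g}|AsnRS", g, "AsnRS")
         for g in scaffold.viral["Imitervirales"] if g != lost]
calls += [AarsCall(f"{g}|IleRS", g, "IleRS") for g in scaffold.rich_clade]
profile = richness_profile(calls, species_tree, scaffold.rich_clade)
print(f"rich clade      : {len(profile.clade_genomes)} genomes, "
      f"{profile.clade_total} aaRS genes")

# The vHGT detector names the foreign-order tip and its implied donor
# clade; the displacement call flags the genome whose gene sits among
# eukaryotes while every close relative kept the vertical viral copy.
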