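"""Dereplicate metagenome-assembled genomes from a pairwise ANI table.

A pair of MAGs joins a cluster when ANI > 98% and the alignment covers
> 25% of the smaller genome (both strict); clusters are single-linkage
connected components, represented by their largest Tara Oceans member.
"""

from aarsphylo.preprocess import ANIRecord, GenomeMeta, dereplicate

ani = [
    ANIRecord("mag_01", "mag_02", ani=99.1, coverage_smaller=41.0),
    ANIRecord("mag_02", "mag_03", ani=98.6, coverage_smaller=28.5),
    ANIRecord("mag_01", "mag_04", ani=99.5, coverage_smaller=22.0),  # low cov
    ANIRecord("mag_05", "mag_06", ani=97.2, coverage_smaller=80.0),  # low ANI
]
meta = [
    GenomeMeta("mag_01", 310_000, project="tara"),
    GenomeMeta("mag_02", 450_000),
    GenomeMeta("mag_03", 120_000, project="tara"),
    GenomeMeta("mag_04", 500_000),
    GenomeMeta("mag_05", 280_000),
    GenomeMeta("mag_06", 260_000),
    GenomeMeta("ref_01", 1_200_000, kind="reference"),
]

result = dereplicate(ani, meta)
for rep, members in sorted(result.clusters.items()):
    print(f"representative {rep}: cluster {members}")
print("references kept apart:", result.references)

# mag_01..03 chain into one cluster (mag_01 represents it: largest Tara
# member); the mag_01/mag_04 pair fails the coverage rule and mag_05/06
# fails the ANI rule, so those genomes stay separate. Reference genomes
# never enter MAG clustering.
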