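"""Aggregate the packaged scenario table and dataset counts.

Reads the per-clade scenario fixture (one row per published clade/branch),
counts distinct aaRS classes per scenario, applies the pre-LECA rule, and
recomputes the headline dataset shares from the counts fixture.
"""

from aarsphylo import counts_report, load_table1_calls, summarize_scenarios

summary = summarize_scenarios(load_table1_calls())
print("distinct classes per scenario:")
for scenario, n in summary.class_counts.items():
    print(f"  {scenario:16s} {n:2d}  {summary.classes_by_scenario[scenario]}")
print(f"pre-LECA classes : {summary.n_pre_leca}  {summary.pre_leca_classes}")

shares = counts_report()
print(f"Imitervirales share of aaRSs : {shares['imitervirales_share_pct']}%")
print(f"AsnRS / IleRS / TyrRS shares : {shares['asnrs_share_pct']}% / "
      f"{shares['ilers_share_pct']}% / {shares['tyrrs_share_pct']}%")

# Seven classes show the proto-eukaryotic sister pattern; TyrRS's nested
# (virus-encompassing-eukaryote) pattern pushes the pre-LECA tally to
# eight. Four classes predate the divergence of major eukaryote lineages
# without firmly reaching LECA.
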