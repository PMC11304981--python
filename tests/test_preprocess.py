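"""Dereplication, trimming, aaRS assignment, contamination filtering."""

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from aarsphylo import (MSA, annotation_map, dereplicate, flag_contamination,
                       parse_newick, trim_alignment)
from aarsphylo.phylo_io import HitRecord, TaxonAnnotation
from aarsphylo.preprocess import (ANIRecord, AarsCall, ContigMeta, GenomeMeta,
                                  assign_aars)


def _meta(genomes, tara=(), reference=()):
    return [GenomeMeta(g, 1000 + 10 * i,
                       "tara" if g in tara else "",
                       "reference" if g in reference else "mag")
            for i, g in enumerate(genomes)]


class TestDereplicate:
    def test_single_edge_merges_pair(self):
        res = dereplicate([ANIRecord("M1", "M2", 99, 30)], _meta(["M1", "M2", "M3"]))
        assert sorted(res.clusters.values()) == [["M1", "M2"], ["M3"]]
        # representative is the larger genome (M2: 1010 bp)
        assert "M2" in res.clusters and res.clusters["M2"] == ["M1", "M2"]

    def test_coverage_at_threshold_adds_no_edge(self):
        res = dereplicate([ANIRecord("M1", "M3", 99, 25)], _meta(["M1", "M3"]))
        assert len(res.clusters) == 2

    def test_ani_at_threshold_adds_no_edge(self):
        res = dereplicate([ANIRecord("M1", "M3", 98, 60)], _meta(["M1", "M3"]))
        assert len(res.clusters) == 2

    def test_chain_forms_one_cluster(self):
        ani = [ANIRecord("M1", "M2", 99, 30), ANIRecord("M2", "M4", 99, 30)]
        res = dereplicate(ani, _meta(["M1", "M2", "M3", "M4"]))
        assert ["M1", "M2", "M4"] in list(res.clusters.values())

    def test_tara_member_preferred_as_representative(self):
        res = dereplicate([ANIRecord("M1", "M2", 99, 30)],
                          _meta(["M1", "M2"], tara={"M1"}))
        assert list(res.clusters) == ["M1"]  # smaller but from Tara

    def test_references_never_clustered(self):
        res = dereplicate([ANIRecord("R1", "M1", 99.9, 99)],
                          _meta(["R1", "M1"], reference={"R1"}))
        assert res.references == ["R1"]
        assert res.clusters == {"M1": ["M1"]}

    def test_unknown_genome_in_ani_table_raises(self):
        with pytest.raises(ValueError, match="not in metadata"):
            dereplicate([ANIRecord("M1", "MX", 99, 30)], _meta(["M1"]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 9), st.integers(0, 9),
                  st.floats(90, 100), st.floats(0, 100)),
        max_size=25))
    def test_clusters_match_networkx_components(self, raw):
        genomes = [f"M{i}" for i in range(10)]
        ani = [ANIRecord(f"M{a}", f"M{b}", x, c) for a, b, x, c in raw if a != b]
        res = dereplicate(ani, _meta(genomes))
        g = nx.Graph()
        g.add_nodes_from(genomes)
        g.add_edges_from((r.genome_a, r.genome_b) for r in ani
                         if r.ani > 98 and r.coverage_smaller > 25)
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(m) for m in res.clusters.values()} == expected
        # partition: every MAG in exactly one cluster, rep is a member
        members = [m for ms in res.clusters.values() for m in ms]
        assert sorted(members) == sorted(genomes)
        assert all(rep in ms for rep, ms in res.clusters.items())
        # rerunning on representatives yields singletons only
        reps = set(res.clusters)
        ani2 = [r for r in ani if r.genome_a in reps and r.genome_b in reps]
        res2 = dereplicate(ani2, _meta(sorted(reps)))
        assert all(len(m) == 1 for m in res2.clusters.values())


class TestTrimAlignment:
    def test_gap_fraction_exactly_at_default_threshold_kept(self):
        msa = MSA(ids=list("abcd"), rows=["-A", "-A", "-A", "AA"])  # col0: 3/4
        _, kept = trim_alignment(msa, 0.75)
        assert kept == [0, 1]

    def test_same_column_removed_at_stringent_threshold(self):
        msa = MSA(ids=list("abcd"), rows=["-A", "-A", "-A", "AA"])
        _, kept = trim_alignment(msa, 0.50)
        assert kept == [1]

    def test_gap_free_alignment_is_identity(self):
        msa = MSA(ids=["a", "b"], rows=["ACD", "ACD"])
        out, kept = trim_alignment(msa)
        assert out.rows == msa.rows and kept == [0, 1, 2]

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            trim_alignment(MSA(ids=[], rows=[]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="A-", min_size=8, max_size=8),
                    min_size=2, max_size=6))
    def test_oracle_idempotence_and_threshold_monotonicity(self, rows):
        msa = MSA(ids=[f"s{i}" for i in range(len(rows))], rows=rows)
        out75, kept75 = trim_alignment(msa, 0.75)
        # oracle: direct column scan
        expect = [c for c in range(8)
                  if sum(r[c] == "-" for r in rows) / len(rows) <= 0.75]
        assert kept75 == expect
        # idempotent at fixed threshold
        out2, kept2 = trim_alignment(out75, 0.75)
        assert out2.rows == out75.rows
        # stringent threshold keeps a subset
        _, kept50 = trim_alignment(msa, 0.50)
        assert set(kept50) <= set(kept75)


class TestAssignAars:
    def _hit(self, q, desc, e, bits, s="s1"):
        return HitRecord(q, s, e, bits, desc)

    def test_best_hit_aars_called(self):
        calls = assign_aars([self._hit("g1", "asparaginyl-tRNA synthetase", 1e-30, 200)])
        assert calls[0].aars_class == "AsnRS"

    def test_evalue_above_threshold_yields_no_call(self):
        assert assign_aars([self._hit("g1", "valyl-tRNA synthetase", 1e-3, 200)]) == []

    def test_only_the_best_hit_counts(self):
        hits = [self._hit("g1", "DNA polymerase", 1e-50, 300, "s1"),
                self._hit("g1", "tryptophanyl-tRNA synthetase", 1e-40, 250, "s2")]
        assert assign_aars(hits) == []

    def test_subtype_note_recorded(self):
        calls = assign_aars([self._hit(
            "g1", "phenylalanine--tRNA ligase alpha subunit", 1e-30, 200)])
        assert calls[0].aars_class == "PheRS" and "alpha" in calls[0].subtype_note

    def test_unknown_class_rejected_on_construction(self):
        with pytest.raises(ValueError):
            AarsCall("g", "G", "FooRS")


class TestFlagContamination:
    ANN = annotation_map([
        TaxonAnnotation("B1", "B1", "bacteria", "not_applicable", "P1"),
        TaxonAnnotation("B2", "B2", "bacteria", "not_applicable", "P1"),
        TaxonAnnotation("v1", "G1", "virus", "not_applicable", "Imitervirales",
                        source="mag"),
        TaxonAnnotation("v2", "G2", "virus", "not_applicable", "Imitervirales",
                        source="mag"),
        TaxonAnnotation("v3", "G3", "virus", "not_applicable", "Imitervirales",
                        source="isolate"),
    ])

    def test_lone_mag_tip_without_viral_signal_flagged(self):
        tree = parse_newick("((B1,v1),B2);")
        contigs = [ContigMeta("c1", "G1", False, False)]
        assert flag_contamination(tree, self.ANN, contigs) == {"v1"}

    def test_core_gene_on_contig_retains_tip(self):
        tree = parse_newick("((B1,v1),B2);")
        contigs = [ContigMeta("c1", "G1", True, False)]
        assert flag_contamination(tree, self.ANN, contigs) == set()

    def test_tip_in_multivirus_clade_never_flagged(self):
        tree = parse_newick("(((v1,v2),B1),B2);")
        contigs = [ContigMeta("c1", "G1", False, False)]
        assert flag_contamination(tree, self.ANN, contigs) == set()

    def test_isolate_tip_never_flagged(self):
        tree = parse_newick("((B1,v3),B2);")
        assert flag_contamination(tree, self.ANN, []) == set()

    def test_missing_contig_metadata_warns_and_retains(self):
        tree = parse_newick("((B1,v1),B2);")
        with pytest.warns(UserWarning, match="no contig metadata"):
            assert flag_contamination(tree, self.ANN, []) == set()
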