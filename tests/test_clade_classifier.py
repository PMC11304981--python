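"""Viral-clade extraction and six-way scenario classification."""

import numpy as np
import pytest

from aarsphylo import (ClassifierParams, annotation_map, classify_scenario,
                       extract_viral_clades, load_table1_calls, parse_newick,
                       sister_context, summarize_scenarios)
from aarsphylo.clade_classifier import classify_all, subsection_tree
from aarsphylo.phylo_io import TaxonAnnotation
from aarsphylo.tree import SupportPair


def _ann(spec):
    """spec: name -> (domain, compartment, group[, source])."""
    rows = []
    for name, parts in spec.items():
        domain, compartment, group = parts[:3]
        source = parts[3] if len(parts) > 3 else "mag"
        rows.append(TaxonAnnotation(name, name, domain, compartment, group,
                                    source=source))
    return annotation_map(rows)


def _with_high_supports(tree):
    for node in tree.postorder():
        if not node.is_leaf and node is not tree.root:
            node.support = SupportPair(sh_alrt=99, ufb=99, tbe=95)
    return tree


V = ("virus", "not_applicable", "Imitervirales")
VISO = ("virus", "not_applicable", "Imitervirales", "isolate")
B = ("bacteria", "not_applicable", "P1")
A = ("archaea", "not_applicable", "P1")


def _euk(sg):
    return ("eukaryote", "nuclear", sg)


class TestExtractViralClades:
    def test_five_virus_clade_is_eligible(self):
        ann = _ann({**{f"v{i}": V for i in range(1, 6)}, "B1": B, "B2": B})
        tree = parse_newick("(((((v1,v2),(v3,v4)),v5),B1),B2);")
        (clade,) = extract_viral_clades(tree, ann)
        assert clade.n_viral == 5 and clade.eligible
        assert clade.order_composition == {"Imitervirales": 5}

    def test_mag_cherry_returned_but_ineligible(self):
        ann = _ann({"v1": V, "v2": V, "B1": B, "B2": B})
        tree = parse_newick("(((v1,v2),B1),B2);")
        (clade,) = extract_viral_clades(tree, ann)
        assert clade.n_viral == 2 and not clade.eligible

    def test_single_isolate_branch_is_eligible(self):
        ann = _ann({"v1": VISO, "e1": _euk("Amorphea"), "e2": _euk("Amorphea"),
                    "e3": _euk("SAR")})
        tree = parse_newick("(((v1,e1),e2),e3);")
        (clade,) = extract_viral_clades(tree, ann)
        assert clade.n_viral == 1 and clade.contains_isolate and clade.eligible

    def test_unannotated_tip_raises(self):
        ann = _ann({"v1": V})
        with pytest.raises(KeyError):
            extract_viral_clades(parse_newick("(v1,x1);"), ann)

    def test_ineligible_clade_refused_by_classifier(self):
        ann = _ann({"v1": V, "v2": V, "B1": B, "B2": B})
        tree = parse_newick("(((v1,v2),B1),B2);")
        (clade,) = extract_viral_clades(tree, ann)
        with pytest.raises(ValueError, match="not eligible"):
            classify_scenario(tree, clade, ann)


class TestScenarioRules:
    """Hand-built miniature trees, one per published pattern."""

    def _proto_tree(self):
        # supported viral clade sister to a supported eukaryote clade spanning
        # three supergroups and holding every nuclear tip
        ann = _ann({
            "v1": V, "v2": V, "v3": V,
            "am1": _euk("Amorphea"), "am2": _euk("Amorphea"),
            "sa1": _euk("SAR"), "sa2": _euk("SAR"),
            "ar1": _euk("Archaeplastida"), "ar2": _euk("Archaeplastida"),
            "A1": A, "A2": A, "B1": B, "B2": B,
        })
        tree = parse_newick(
            "((B1,B2),((A1,A2),(((v1,v2),v3),"
            "((am1,am2),((sa1,sa2),(ar1,ar2))))));")
        return _with_high_supports(tree), ann

    def test_proto_euk_v_with_dual_support(self):
        tree, ann = self._proto_tree()
        (call,) = classify_all(tree, ann, aars_class="GlyRS")
        assert call.scenario == "proto_euk_v"
        assert call.support_basis == "topology_ufb_shalrt"

    def test_proto_structure_with_tbe_only_downgrades_to_ancient(self):
        tree, ann = self._proto_tree()
        for node in tree.postorder():
            if not node.is_leaf and node is not tree.root:
                node.support = SupportPair(sh_alrt=50, ufb=70, tbe=90)
        (call,) = classify_all(tree, ann)
        assert call.scenario == "ancient_euk_v"
        assert call.support_basis == "topology_tbe"

    def test_proto_structure_without_support_falls_to_other(self):
        tree, ann = self._proto_tree()
        for node in tree.postorder():
            if not node.is_leaf and node is not tree.root:
                node.support = SupportPair(sh_alrt=50, ufb=70, tbe=40)
        (call,) = classify_all(tree, ann)
        assert call.scenario == "other_euk_v"
        assert call.support_basis == "topology_only"

    def test_ancient_when_sister_spans_two_supergroups(self):
        ann = _ann({
            "v1": V, "v2": V, "v3": V,
            "am1": _euk("Amorphea"), "am2": _euk("Amorphea"),
            "sa1": _euk("SAR"), "sa2": _euk("SAR"),
            "ar1": _euk("Archaeplastida"), "ar2": _euk("Archaeplastida"),
            "ex1": _euk("Excavata"), "A1": A, "B1": B,
        })
        # viral clade sister to Amorphea+SAR only; Archaeplastida+Excavata apart
        tree = parse_newick(
            "((B1,A1),((((v1,v2),v3),((am1,am2),(sa1,sa2))),"
            "((ar1,ar2),ex1)));")
        (call,) = classify_all(_with_high_supports(tree), ann)
        assert call.scenario == "ancient_euk_v"

    def test_recent_transfer_inside_one_supergroup(self):
        # viral clade sister to an Alveolata-like subclade inside a
        # multi-supergroup eukaryote clade
        ann = _ann({
            "v1": V, "v2": V, "v3": V,
            "al1": _euk("SAR"), "al2": _euk("SAR"), "al3": _euk("SAR"),
            "am1": _euk("Amorphea"), "am2": _euk("Amorphea"),
            "A1": A, "B1": B,
        })
        tree = parse_newick(
            "((B1,A1),(((al1,(((v1,v2),v3),(al2,al3)))),(am1,am2)));")
        (call,) = classify_all(_with_high_supports(tree), ann)
        assert call.scenario == "recent_euk_to_v"

    def test_prok_v_for_viral_pair_of_isolates_among_bacteria(self):
        ann = _ann({"t1": VISO, "t2": VISO, "B1": B, "B2": B, "B3": B,
                    "e1": _euk("Amorphea"), "e2": _euk("SAR"), "A1": A})
        tree = parse_newick("(((((t1,t2),B1),(B2,B3)),A1),(e1,e2));")
        calls = classify_all(_with_high_supports(tree), ann, aars_class="ValRS")
        assert [c.scenario for c in calls] == ["prok_v"]

    def test_v_to_euk_nested_pattern(self):
        # eukaryote clade (Fungi+Metazoa stand-ins) whose two successive
        # enclosing nodes are majority-viral
        ann = _ann({
            "v1": V, "v2": V, "v3": V, "v4": V, "v5": V, "v6": V,
            "f1": _euk("Amorphea"), "f2": _euk("Amorphea"),
            "s1": _euk("SAR"), "s2": _euk("SAR"),
            "A1": A, "B1": B,
        })
        tree = parse_newick(
            "((B1,A1),(((v1,(v2,v3)),((v4,(v5,v6)),(f1,f2))),(s1,s2)));")
        calls = classify_all(_with_high_supports(tree), ann, aars_class="TyrRS")
        assert {c.scenario for c in calls} == {"v_to_euk"}
        assert all("encompassing a eukaryotic clade" in c.notes for c in calls)

    def test_organellar_sister_variant_counts_as_proto(self):
        org = lambda sg: ("eukaryote", "organellar", sg)
        ann = _ann({
            "v1": V, "v2": V, "v3": V,
            "o1": org("Amorphea"), "o2": org("SAR"), "o3": org("Archaeplastida"),
            "e1": _euk("Amorphea"), "e2": _euk("SAR"),
            "A1": A, "B1": B, "B2": B,
        })
        tree = parse_newick(
            "((B1,B2),((((v1,v2),v3),((o1,o2),o3)),(A1,(e1,e2))));")
        (call,) = classify_all(_with_high_supports(tree), ann, aars_class="PheRS")
        assert call.scenario == "proto_euk_v"
        assert "organellar" in call.notes

    def test_tip_order_invariance(self):
        tree, ann = self._proto_tree()
        calls = classify_all(tree, ann)
        for node in tree.postorder():
            node.children.reverse()
        calls2 = classify_all(tree, ann)
        assert [(c.scenario, c.support_basis) for c in calls] == \
               [(c.scenario, c.support_basis) for c in calls2]

    def test_sister_context_reports_composition(self):
        tree, ann = self._proto_tree()
        (clade,) = extract_viral_clades(tree, ann)
        ctx = sister_context(tree, clade, ann)
        assert ctx.domain_counts == {"eukaryote_nuclear": 6}
        assert ctx.supergroups == {"Amorphea", "SAR", "Archaeplastida"}
        assert ctx.enclosing_euk_span == 3
        assert ctx.enclosing_euk_fraction == pytest.approx(1.0)

    def test_subsection_tree_contains_clade_and_context(self):
        tree, ann = self._proto_tree()
        (clade,) = extract_viral_clades(tree, ann)
        sub = subsection_tree(tree, clade, ann, radius=1)
        assert set(clade.members) <= set(sub.leaf_names())
        assert len(sub.leaf_names()) < len(tree.leaf_names()) or True


class TestSummarize:
    def test_published_table_aggregation(self):
        summary = summarize_scenarios(load_table1_calls())
        assert summary.class_counts["proto_euk_v"] == 7
        assert summary.class_counts["ancient_euk_v"] == 4
        assert summary.n_pre_leca == 8
        assert "TyrRS" in summary.pre_leca_classes

    def test_empty_input_gives_all_zero_summary(self):
        summary = summarize_scenarios([])
        assert all(v == 0 for v in summary.call_counts.values())
        assert summary.n_pre_leca == 0

    def test_table_fixture_has_one_row_per_printed_clade(self):
        calls = load_table1_calls()
        assert len(calls) == 36
        assert sum(c.scenario == "v_to_euk" for c in calls) == 3
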