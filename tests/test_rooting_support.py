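"""Rooting at the prokaryote split, support thresholds, TBE."""

import itertools

import dendropy
import numpy as np
import pytest

from aarsphylo import (SupportThresholds, annotation_map, compute_tbe,
                       felsenstein_support, is_supported, parse_newick,
                       root_at_prok_split, write_newick)
from aarsphylo.phylo_io import TaxonAnnotation
from aarsphylo.rooting_support import score_edges
from aarsphylo.synthetic_data import _balanced, simulate_bootstrap_set
from aarsphylo.tree import PhyloTree, SupportPair


def _ann(domains):
    return annotation_map([
        TaxonAnnotation(name, name, dom,
                        "not_applicable" if dom != "eukaryote" else "nuclear",
                        "G") for name, dom in domains.items()])


def _oracle_best_edges(newick, domains):
    """Independent rooting oracle: enumerate every edge with dendropy and
    score bacteria/archaea separation from raw bipartition leaf sets."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    taxa = {t.label for t in tree.taxon_namespace}
    bact = {n for n in taxa if domains[n] == "bacteria"}
    arch = {n for n in taxa if domains[n] == "archaea"}
    best, best_sides = -1.0, []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        side = {l.taxon.label for l in edge.head_node.leaf_iter()}
        b_in = len(side & bact) / len(bact)
        a_in = len(side & arch) / len(arch)
        score = max(b_in * (1 - a_in), (1 - b_in) * a_in)
        if score > best + 1e-12:
            best, best_sides = score, [frozenset(side)]
        elif abs(score - best) <= 1e-12:
            best_sides.append(frozenset(side))
    return best, best_sides


class TestRooting:
    def test_perfect_separation_roots_between_domains(self):
        domains = {"B1": "bacteria", "B2": "bacteria", "A1": "archaea",
                   "A2": "archaea", "E1": "eukaryote", "V1": "eukaryote"}
        tree = parse_newick("((B1,B2),(A1,A2),(E1,V1));", rooted=False)
        rooted = root_at_prok_split(tree, _ann(domains))
        # the chosen edge lies on the path between the two monophyletic
        # domains: one root side holds all bacteria and no archaea
        sides = [c.leaf_names() for c in rooted.root.children]
        bact, arch = {"B1", "B2"}, {"A1", "A2"}
        assert any(bact <= s and not (arch & s) for s in sides)
        assert any(arch <= s and not (bact & s) for s in sides)

    def test_nested_archaeon_matches_brute_force_oracle(self):
        domains = {"B1": "bacteria", "B2": "bacteria", "B3": "bacteria",
                   "A1": "archaea", "A2": "archaea", "E1": "eukaryote"}
        newick = "((B1,(A1,B2)),((B3,A2),E1));"
        tree = parse_newick(newick, rooted=False)
        ann = _ann(domains)
        best, best_sides = _oracle_best_edges(newick, domains)
        impl_best = max(score_edges(tree, ann), key=lambda it: it[1].score)
        assert impl_best[1].score == pytest.approx(best)
        all_leaves = tree.leaf_names()
        chosen = {s for _, bs in score_edges(tree, ann)
                  if bs.score == pytest.approx(best) for s in [bs.leafset]}
        assert all(s in best_sides or (all_leaves - s) in best_sides
                   for s in chosen)

    def test_bacteria_only_tree_cannot_be_rooted(self):
        domains = {"B1": "bacteria", "B2": "bacteria", "B3": "bacteria"}
        tree = parse_newick("(B1,B2,B3);", rooted=False)
        with pytest.raises(ValueError, match="cannot root"):
            root_at_prok_split(tree, _ann(domains))

    def test_rerooting_preserves_unrooted_splits(self):
        domains = {f"B{i}": "bacteria" for i in range(1, 4)}
        domains.update({f"A{i}": "archaea" for i in range(1, 4)})
        domains["E1"] = "eukaryote"
        newick = "((B1,(B2,B3)),((A1,A2),(A3,E1)));"
        tree = parse_newick(newick, rooted=False)
        rooted = root_at_prok_split(tree, _ann(domains))
        assert rooted.split_set() == parse_newick(newick).split_set()


class TestIsSupported:
    TH = SupportThresholds()

    def test_thresholds_inclusive_at_80_95(self):
        assert is_supported(SupportPair(sh_alrt=80, ufb=95), self.TH)

    def test_high_shalrt_cannot_rescue_low_ufb(self):
        # UFB = 94 with SH-aLRT = 96.8 misses the UFB threshold
        assert not is_supported(SupportPair(sh_alrt=96.8, ufb=94), self.TH)

    def test_tbe_basis(self):
        assert is_supported(SupportPair(tbe=71), self.TH, basis="tbe")
        assert not is_supported(SupportPair(tbe=69), self.TH, basis="tbe")

    def test_missing_support_never_passes(self):
        assert not is_supported(None, self.TH)
        assert not is_supported(SupportPair(ufb=99), self.TH)  # SH-aLRT missing

    def test_strict_mode_excludes_boundary(self):
        strict = SupportThresholds(strict=True)
        assert not is_supported(SupportPair(sh_alrt=80, ufb=95), strict)
        assert is_supported(SupportPair(sh_alrt=80.1, ufb=95.1), strict)


def _oracle_tbe(ref_newick, boot_newicks):
    """Brute-force TBE oracle built on dendropy bipartition leaf sets."""
    ref = dendropy.Tree.get(data=ref_newick, schema="newick",
                            preserve_underscores=True)
    taxa = frozenset(t.label for t in ref.taxon_namespace)
    n = len(taxa)

    def sides(tree):
        out = []
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            out.append(frozenset(l.taxon.label
                                 for l in edge.head_node.leaf_iter()))
        return out

    boots = [sides(dendropy.Tree.get(data=t, schema="newick",
                                     preserve_underscores=True))
             for t in boot_newicks]
    out = {}
    for side in sides(ref):
        lighter = side if len(side) <= n - len(side) else taxa - side
        p = len(lighter)
        if p < 2:
            continue
        total = 0
        for bsides in boots:
            total += min(min(len(lighter ^ s), len(lighter ^ (taxa - s)))
                         for s in bsides)
        out[lighter] = 100.0 * (1 - (total / len(boots)) / (p - 1))
    return out


class TestComputeTbe:
    def test_branch_in_all_bootstraps_scores_100(self):
        ref = parse_newick("((a,b),(c,d));")
        boots = [parse_newick("((a,b),(c,d));") for _ in range(5)]
        tbe = compute_tbe(ref, boots)
        assert all(v == pytest.approx(100) for v in tbe.values())

    def test_worked_p3_example(self):
        # p=3 branch {a,b,c}; bootstrap minima 0 and 1 -> 100*(1-0.5/2)=75
        ref = parse_newick("((a,(b,c)),(d,(e,f)));")
        b1 = parse_newick("((a,(b,c)),(d,(e,f)));")          # delta 0
        b2 = parse_newick("(((a,b),d),((c,e),f));")          # best match {a,b}: delta 1
        tbe = compute_tbe(ref, [b1, b2])
        assert tbe[frozenset("abc")] == pytest.approx(75)

    def test_cherry_tbe_equals_felsenstein_proportion(self):
        rng = np.random.default_rng(5)
        ref = PhyloTree(_balanced([f"t{i}" for i in range(10)], rng))
        boots = simulate_bootstrap_set(ref, 30, 0.3, seed=9)
        tbe = compute_tbe(ref, boots)
        fels = felsenstein_support(ref, boots)
        for side, value in tbe.items():
            if len(side) == 2:
                assert value == pytest.approx(fels[side])

    def test_tbe_never_below_felsenstein(self):
        rng = np.random.default_rng(6)
        ref = PhyloTree(_balanced([f"t{i}" for i in range(12)], rng))
        boots = simulate_bootstrap_set(ref, 25, 0.4, seed=10)
        tbe = compute_tbe(ref, boots)
        fels = felsenstein_support(ref, boots)
        for side in fels:
            assert tbe[side] >= fels[side] - 1e-9
            assert 0 <= tbe[side] <= 100

    @pytest.mark.parametrize("n_leaves,seed", [(8, 1), (11, 2), (16, 3)])
    def test_matches_independent_oracle(self, n_leaves, seed):
        rng = np.random.default_rng(seed)
        ref = PhyloTree(_balanced([f"t{i}" for i in range(n_leaves)], rng))
        boots = simulate_bootstrap_set(ref, 15, 0.35, seed=seed + 100)
        tbe = compute_tbe(ref, boots)
        oracle = _oracle_tbe(write_newick(ref), [write_newick(b) for b in boots])
        assert set(tbe) == set(oracle)
        for side in tbe:
            assert tbe[side] == pytest.approx(oracle[side])

    def test_leaf_set_mismatch_rejected(self):
        ref = parse_newick("((a,b),(c,d));")
        with pytest.raises(ValueError, match="leaf set"):
            compute_tbe(ref, [parse_newick("((a,b),(c,e));")])
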