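"""Newick I/O, rooting, collapsing, clade assignment, presence/absence
summaries and topology congruence."""

import random

import pandas as pd
import pytest

from pks3evo.trees import (
    assign_phylo_clades,
    class_presence_absence,
    collapse_weak_edges,
    parse_newick,
    read_tree,
    root_tree,
    to_newick,
    topology_congruence,
    write_tree,
)

from oracles import naive_bipartitions, random_topology


def topologies_equal(a, b):
    return naive_bipartitions(a) == naive_bipartitions(b) and set(
        a.leaf_labels()
    ) == set(b.leaf_labels())


class TestNewickIO:
    def test_round_trip_small(self, tmp_path):
        tree = parse_newick("((A:1,B:2)97:0.5,(C:1,D:1)99:0.5);")
        path = tmp_path / "t.nwk"
        write_tree(tree, path)
        back = read_tree(path)
        assert topologies_equal(tree, back)
        assert [n.support for n in back.postorder() if not n.is_leaf and not n.is_root] == [97.0, 99.0]

    def test_supports_preserved_on_larger_tree(self, tmp_path):
        rng = random.Random(7)
        tree = random_topology([f"L{i}" for i in range(50)], rng)
        for i, node in enumerate(tree.postorder()):
            if not node.is_leaf and not node.is_root:
                node.support = float(50 + (i % 51))
        path = tmp_path / "t.nwk"
        write_tree(tree, path)
        back = read_tree(path)
        assert topologies_equal(tree, back)
        orig = sorted(
            n.support for n in tree.postorder() if n.support is not None
        )
        readback = sorted(
            n.support for n in back.postorder() if n.support is not None
        )
        assert orig == readback

    @pytest.mark.parametrize(
        "newick, dialect, expected",
        [
            ("((A,B)97,C);", "percent", 97.0),
            ("((A,B)0.97,C);", "fraction", 97.0),
        ],
    )
    def test_support_dialect_autodetection(self, newick, dialect, expected):
        tree = parse_newick(newick)
        assert tree.support_dialect == dialect
        internal = [n for n in tree.postorder() if not n.is_leaf and not n.is_root]
        assert internal[0].support == pytest.approx(expected)

    def test_unparseable_newick_raises(self):
        with pytest.raises(ValueError, match="unparseable"):
            parse_newick("((A,B);")


class TestRooting:
    def test_single_leaf_outgroup(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        rooted = root_tree(tree, "A")
        assert rooted.children[0].leaf_labels() == ["A"]
        assert set(rooted.children[1].leaf_labels()) == {"B", "C", "D", "E"}

    def test_rooting_is_idempotent(self):
        tree = parse_newick("((A,B),(C,(D,E)));")
        once = root_tree(tree, ["D", "E"])
        twice = root_tree(once, ["D", "E"])
        assert to_newick(once, include_supports=False) == to_newick(
            twice, include_supports=False
        )

    def test_rooted_split_matches_bipartition_listing(self):
        # the outgroup bipartition must exist in the unrooted split set,
        # and rooting must place exactly that split at the root
        tree = parse_newick("(((A,B),C),((D,E),F));")
        og = {"D", "E", "F"}
        assert frozenset(og) in naive_bipartitions(tree) or frozenset(
            set(tree.leaf_labels()) - og
        ) in naive_bipartitions(tree)
        rooted = root_tree(tree, og)
        sides = {frozenset(ch.leaf_labels()) for ch in rooted.children}
        assert sides == {frozenset(og), frozenset({"A", "B", "C"})}

    def test_non_monophyletic_outgroup_lists_violators(self):
        tree = parse_newick("(((A,B),C),(D,E));")
        with pytest.raises(ValueError, match="not monophyletic"):
            root_tree(tree, ["A", "C"])

    def test_rooting_preserves_all_leaves(self):
        tree = parse_newick("((A,(B,C)),((D,E),(F,G)));")
        rooted = root_tree(tree, ["F", "G"])
        assert sorted(rooted.leaf_labels()) == sorted(tree.leaf_labels())


class TestCollapse:
    def test_all_strong_is_identity(self):
        tree = parse_newick("(((A,B)99,C)98,D);")
        out = collapse_weak_edges(tree, 98)
        assert topologies_equal(tree, out)

    def test_all_weak_gives_star(self):
        tree = parse_newick("(((A,B)50,C)60,(D,E)70);")
        out = collapse_weak_edges(tree, 98)
        assert len(out.children) == 5
        assert all(c.is_leaf for c in out.children)

    def test_mixed_supports_match_manual_contraction(self):
        # contract the 90 and 40 edges by hand: ((A,B),C,D,(E,F)) with the
        # 99 and 98 clades kept
        tree = parse_newick("((((A,B)99,C)90,D)40,(E,F)98);")
        out = collapse_weak_edges(tree, 98)
        kept = {
            frozenset(n.leaf_labels())
            for n in out.postorder()
            if not n.is_leaf and not n.is_root
        }
        assert kept == {frozenset({"A", "B"}), frozenset({"E", "F"})}
        assert len(out.children) == 4

    def test_edge_exactly_at_threshold_survives(self):
        tree = parse_newick("((A,B)98,C);")
        out = collapse_weak_edges(tree, 98)
        assert topologies_equal(tree, out)

    def test_collapse_is_idempotent(self):
        tree = parse_newick("((((A,B)99,C)90,D)40,(E,F)98);")
        once = collapse_weak_edges(tree, 98)
        twice = collapse_weak_edges(once, 98)
        assert to_newick(once) == to_newick(twice)


class TestCladeAssignment:
    def test_two_balanced_halves(self):
        tree = parse_newick("(((A,B)100,(C,D)100)100,((E,F)100,(G,H)100)100);")
        got = assign_phylo_clades(tree, support_threshold=95, min_clade_size=2)
        # the two root children are the maximal supported clades
        assert {k for k, v in got.items() if v == "clade1"} == {"A", "B", "C", "D"}
        assert {k for k, v in got.items() if v == "clade2"} == {"E", "F", "G", "H"}

    def test_eight_clades_under_weak_backbone(self):
        # eight perfectly supported cherries joined by a weak backbone
        cherries = [f"(L{i}a,L{i}b)100" for i in range(8)]
        backbone = cherries[0]
        for ch in cherries[1:]:
            backbone = f"({backbone},{ch})10"
        tree = parse_newick(backbone + ";")
        got = assign_phylo_clades(tree, support_threshold=95, min_clade_size=2)
        clades = {v for v in got.values() if v}
        assert len(clades) == 8
        for i in range(8):
            assert got[f"L{i}a"] == got[f"L{i}b"]

    def test_lone_leaves_stay_unassigned(self):
        tree = parse_newick("(((A,B)100,C)10,D);")
        got = assign_phylo_clades(tree, support_threshold=95, min_clade_size=2)
        assert got["C"] is None and got["D"] is None
        assert got["A"] == got["B"] == "clade1"

    def test_rotation_invariance(self):
        a = parse_newick("(((A,B)100,(C,D)100)20,((E,F)100,G)20);")
        b = parse_newick("((G,(F,E)100)20,((D,C)100,(B,A)100)20);")
        assert assign_phylo_clades(a) == assign_phylo_clades(b)

    def test_seed_taxa_mode(self):
        tree = parse_newick("(((A,B)100,C)100,(D,E)100);")
        got = assign_phylo_clades(tree, seed_taxa={"west": ["A", "C"], "east": ["D", "E"]})
        assert got == {"A": "west", "B": "west", "C": "west",
                       "D": "east", "E": "east"}


class TestPresenceAbsence:
    @staticmethod
    def _tables(n_genomes, with_gene):
        tax = pd.DataFrame(
            {
                "genome_id": [f"g{i}" for i in range(n_genomes)],
                "kingdom": "Fungi",
                "phylum": ["P1" if i % 2 else "P2" for i in range(n_genomes)],
                "class": ["C1" if i % 4 < 2 else "C2" for i in range(n_genomes)],
            }
        )
        genes = pd.DataFrame(
            {
                "genome_id": [f"g{i}" for i in with_gene],
                "classification": "type3_pks",
            }
        )
        return tax, genes

    def test_all_genomes_with_gene(self):
        tax, genes = self._tables(10, range(10))
        out = class_presence_absence(tax, genes)
        overall = out[out["level"] == "overall"].iloc[0]
        assert overall["percent_with"] == 100 and overall["n_without"] == 0

    def test_empty_gene_list(self):
        tax, genes = self._tables(10, [])
        out = class_presence_absence(tax, genes)
        assert (out["percent_with"] == 0).all()
        assert (out["n_with"] == 0).all()

    def test_counts_sum_to_taxonomy_size(self):
        tax, genes = self._tables(37, range(0, 37, 3))
        out = class_presence_absence(tax, genes)
        overall = out[out["level"] == "overall"].iloc[0]
        assert overall["n_with"] + overall["n_without"] == 37
        classes = out[out["level"] == "class"]
        assert (classes["n_with"] + classes["n_without"]).sum() == 37

    def test_missing_taxonomy_goes_to_unclassified_with_warning(self):
        tax, genes = self._tables(4, range(4))
        genes = pd.concat(
            [genes, pd.DataFrame([{"genome_id": "mystery",
                                   "classification": "type3_pks"}])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="unclassified"):
            out = class_presence_absence(tax, genes)
        unc = out[(out["level"] == "class") & (out["name"] == "unclassified")]
        assert len(unc) == 1 and unc.iloc[0]["n_with"] == 1


class TestTopologyCongruence:
    def test_tree_vs_itself_is_zero(self):
        tree = parse_newick("(((A,B),C),((D,E),F));")
        pairing = {lab: lab for lab in tree.leaf_labels()}
        assert topology_congruence(tree, tree, pairing) == 0.0

    def test_caterpillar_vs_mirror_matches_bipartition_count(self):
        labels = [f"T{i}" for i in range(6)]
        cat = parse_newick("(((((T0,T1),T2),T3),T4),T5);")
        mirror = parse_newick("(((((T5,T4),T3),T2),T1),T0);")
        pairing = {lab: lab for lab in labels}
        got = topology_congruence(cat, mirror, pairing)
        # brute-force: symmetric difference of the two split sets
        sa, sb = naive_bipartitions(cat), naive_bipartitions(mirror)
        assert got == pytest.approx(len(sa ^ sb) / (len(sa) + len(sb)))
        # mirrored caterpillar has the same unrooted topology
        assert got == 0.0

    def test_conflicting_topologies_reach_one(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        pairing = {lab: lab for lab in "ABCD"}
        assert topology_congruence(a, b, pairing) == 1.0

    def test_random_pruning_stays_in_unit_interval(self):
        rng = random.Random(3)
        labels = [f"x{i}" for i in range(12)]
        a = random_topology(labels, rng)
        b = random_topology(labels, rng)
        for _ in range(10):
            subset = rng.sample(labels, rng.randint(4, 12))
            val = topology_congruence(a, b, {s: s for s in subset})
            assert 0.0 <= val <= 1.0

    def test_relabeling_through_pairing(self):
        a = parse_newick("(((a1,a2),a3),a4);")
        b = parse_newick("(((b1,b2),b3),b4);")
        pairing = {"a1": "b1", "a2": "b2", "a3": "b3", "a4": "b4"}
        assert topology_congruence(a, b, pairing) == 0.0

    def test_fewer_than_four_leaves_is_an_error(self):
        a = parse_newick("((A,B),C);")
        with pytest.raises(ValueError, match="at least 4"):
            topology_congruence(a, a, {"A": "A", "B": "B", "C": "C"})
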