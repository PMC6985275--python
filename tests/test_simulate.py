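"""Simulator ground truth: species trees, gene families, support
degradation, BGC content and fixture round-trips."""

import filecmp
import math
from pathlib import Path

import numpy as np
import pytest

from pks3evo.bgc import bgc_distance, read_bgc_table, write_bgc_table
from pks3evo.config import PipelineConfig
from pks3evo.pipeline import simulate_dataset
from pks3evo.simulate import (
    CladeProfile,
    degrade_gene_tree,
    emit_fixtures,
    simulate_clade_bgcs,
    simulate_gene_family,
    simulate_species_tree,
    total_branch_length,
)
from pks3evo.trees import read_tree, topology_congruence


def leaf_heights(tree):
    heights = []

    def walk(node, h):
        h = h + (node.length or 0.0)
        if node.is_leaf:
            heights.append(h)
        for ch in node.children:
            walk(ch, h)

    walk(tree, 0.0)
    return heights


class TestSpeciesTree:
    def test_two_species_is_an_equal_height_cherry(self):
        tree = simulate_species_tree(2, 1.0, 0.0, seed=5)
        assert len(tree.leaves()) == 2
        h = leaf_heights(tree)
        assert h[0] == pytest.approx(h[1], abs=1e-12)

    def test_sixteen_species_binary_node_count(self):
        tree = simulate_species_tree(16, 1.0, 0.0, seed=1)
        assert len(tree.leaves()) == 16
        assert len(tree.internal_nodes()) == 15

    def test_ultrametric_bookkeeping_over_replicates(self):
        # with extinction in play: always n-1 internal nodes, leaf heights
        # identical within numerical noise
        for rep in range(1000):
            tree = simulate_species_tree(8, 1.0, 0.5, seed=rep)
            assert len(tree.leaves()) == 8
            assert len(tree.internal_nodes()) == 7
            h = leaf_heights(tree)
            assert float(np.var(h)) < 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 1.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            simulate_species_tree(4, 0.0, 0.0, seed=0)

    def test_resample_cap_reported(self):
        with pytest.raises(RuntimeError, match="within 3 resamples"):
            # death dominates birth: extinction nearly certain
            simulate_species_tree(12, 0.001, 50.0, seed=0, max_resamples=3)


class TestGeneFamily:
    def test_no_events_gives_congruent_tree(self, sim_species16):
        gtree, hist = simulate_gene_family(sim_species16, 0, 0, 0, seed=3)
        assert (hist.n_duplications, hist.n_transfers, hist.n_losses) == (0, 0, 0)
        pairing = {f"{s}_1": s for s in sim_species16.leaf_labels()}
        assert topology_congruence(gtree, sim_species16, pairing) == 0.0

    def test_duplication_count_matches_poisson_expectation(self):
        # loss = transfer = 0, small dup rate: E[visible dups] ~= rate * L
        tree = simulate_species_tree(8, 1.0, 0.0, seed=11)
        length = total_branch_length(tree)
        rate = 0.02 / length * 8  # keep the expectation small but not tiny
        counts = []
        for rep in range(2000):
            _, hist = simulate_gene_family(tree, rate, 0, 0, seed=rep)
            counts.append(hist.dups_visible)
        expected = rate * length
        mean = float(np.mean(counts))
        se = float(np.std(counts, ddof=1)) / math.sqrt(len(counts))
        assert abs(mean - expected) <= 3 * se + 0.01 * expected

    def test_transfers_connect_time_overlapping_edges(self, sim_species16):
        # every recorded transfer joins two species edges alive at the
        # event time — check the edge time intervals directly
        spans = {}
        for node in sim_species16.postorder():
            if node.parent is not None:
                spans[node.label] = (node.parent.time, node.time)
        checked = 0
        for rep in range(500):
            _, hist = simulate_gene_family(
                sim_species16, 0, 0.08, 0, seed=rep
            )
            for ev in hist.transfers:
                d0, d1 = spans[ev.donor]
                r0, r1 = spans[ev.recipient]
                assert d0 < ev.time < d1
                assert r0 < ev.time < r1
                checked += 1
        assert checked > 100

    def test_event_counts_equal_event_lists(self, sim_species16):
        for rep in range(50):
            _, hist = simulate_gene_family(
                sim_species16, 0.1, 0.05, 0.08, seed=rep
            )
            assert hist.n_duplications == len(hist.duplications)
            assert hist.n_transfers == len(hist.transfers)
            assert hist.n_losses == len(hist.losses)
            assert hist.dups_visible <= hist.n_duplications
            assert hist.transfers_visible <= hist.n_transfers

    def test_extinct_family_returns_none_with_history(self, sim_species16):
        for rep in range(200):
            gtree, hist = simulate_gene_family(
                sim_species16, 0, 0, 5.0, seed=rep
            )
            if gtree is None:
                assert hist.n_losses > 0
                break
        else:
            pytest.fail("no extinct family found at a huge loss rate")


class TestDegrade:
    def test_zero_fraction_keeps_all_edges_strong(self, sim_species16):
        gtree, _ = simulate_gene_family(sim_species16, 0, 0, 0, seed=2)
        out = degrade_gene_tree(gtree, 0.0, seed=9)
        supports = [
            n.support for n in out.postorder() if not n.is_leaf and not n.is_root
        ]
        assert supports and all(s >= 98 for s in supports)

    def test_full_fraction_collapses_to_star(self, sim_species16):
        from pks3evo.trees import collapse_weak_edges

        gtree, _ = simulate_gene_family(sim_species16, 0, 0, 0, seed=2)
        out = degrade_gene_tree(gtree, 1.0, seed=9)
        star = collapse_weak_edges(out, 98)
        assert len(star.children) == len(gtree.leaves())

    def test_exact_weak_edge_count(self):
        import random

        from oracles import random_topology

        tree = random_topology([f"S{i}_1" for i in range(50)], random.Random(4))
        out = degrade_gene_tree(tree, 0.3, seed=13)
        internal = [
            n for n in out.postorder() if not n.is_leaf and not n.is_root
        ]
        n_weak = sum(1 for n in internal if n.support < 98)
        assert n_weak == round(0.3 * len(internal))

    def test_leaf_set_unchanged(self, sim_species16):
        gtree, _ = simulate_gene_family(sim_species16, 0.1, 0.05, 0.05, seed=4)
        out = degrade_gene_tree(gtree, 0.5, seed=1)
        assert sorted(out.leaf_labels()) == sorted(gtree.leaf_labels())


class TestCladeBGCs:
    def test_deterministic_profile_gives_identical_content(self):
        profile = CladeProfile(
            clade_id="cladeA",
            core_pool={"PF00067": 1.0, "PF07690": 1.0},
            noise_pool=(),
        )
        bgcs, model = simulate_clade_bgcs([profile], 6, 0.0, seed=0)
        first = bgcs[0].domain_types()
        assert all(r.domain_types() == first for r in bgcs)
        for other in bgcs[1:]:
            assert bgc_distance(bgcs[0], other, similarity=model).distance == (
                pytest.approx(0.0)
            )

    def test_each_bgc_has_exactly_one_anchor_gene(self):
        profiles = [
            CladeProfile("c1", core_pool={"PF00067": 0.5}),
            CladeProfile("c2", core_pool={"PF07690": 0.5}),
        ]
        bgcs, _ = simulate_clade_bgcs(profiles, 10, 0.2, seed=3)
        for rec in bgcs:
            assert sum(1 for g in rec.genes if g.anchor) == 1

    def test_disjoint_pools_bound_cross_clade_jaccard(self):
        p1 = CladeProfile(
            "c1", anchor_domains=("PF00195", "PF02797"),
            core_pool={"PF00067": 1.0, "PF00172": 1.0}, noise_pool=(),
        )
        p2 = CladeProfile(
            "c2", anchor_domains=("ANCH2A", "ANCH2B"),
            core_pool={"PF07690": 1.0, "PF00005": 1.0}, noise_pool=(),
        )
        bgcs, _ = simulate_clade_bgcs([p1, p2], 5, 0.0, seed=1)
        # enumeration bound: no shared anchors, disjoint tailoring pools
        # -> zero shared types out of at least 8 in the union
        for a in bgcs[:5]:
            for b in bgcs[5:]:
                j = bgc_distance(a, b).jaccard
                assert j == 0.0

    def test_inclusion_probability_recovered_binomially(self):
        p = 0.5
        n = 400
        profile = CladeProfile("c1", core_pool={"PF00067": p}, noise_pool=())
        bgcs, _ = simulate_clade_bgcs([profile], n, 0.0, seed=17)
        frac = sum("PF00067" in r.domain_types() for r in bgcs) / n
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)


class TestFixtures:
    def test_round_trips(self, tmp_path, sim_species16):
        cfg = PipelineConfig(
            seed=7, n_species=8, n_families=2, n_clades=2,
            n_bgc_per_clade=3, out_dir=str(tmp_path / "x"),
        )
        bundle = simulate_dataset(cfg)
        paths = emit_fixtures(bundle, tmp_path / "fx")
        # tree round-trip
        back = read_tree(paths["species_tree"])
        assert sorted(back.leaf_labels()) == sorted(
            bundle.species_tree.leaf_labels()
        )
        from oracles import naive_bipartitions

        assert naive_bipartitions(back) == naive_bipartitions(
            bundle.species_tree
        )
        # BGC table round-trip
        back_bgcs = read_bgc_table(paths["bgcs"])
        assert len(back_bgcs) == len(bundle.bgcs)
        for orig, rt in zip(bundle.bgcs, back_bgcs):
            assert rt.bgc_id == orig.bgc_id
            assert rt.genome_id == orig.genome_id
            assert [g.domains for g in rt.genes] == [
                g.domains for g in orig.genes
            ]
            assert [g.core for g in rt.genes] == [g.core for g in orig.genes]
        # taxonomy round-trip
        import pandas as pd

        tax = pd.read_csv(paths["taxonomy"], sep="\t")
        assert tax.equals(bundle.taxonomy)

    def test_identical_seed_gives_byte_identical_bundles(self, tmp_path):
        cfg = PipelineConfig(
            seed=11, n_species=8, n_families=2, n_clades=2,
            n_bgc_per_clade=3, out_dir=str(tmp_path / "unused"),
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        emit_fixtures(simulate_dataset(cfg), d1)
        emit_fixtures(simulate_dataset(cfg), d2)
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
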