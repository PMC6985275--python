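"""Reconciliation: worked instances, brute-force oracle equivalence,
limits, monotonicity and the independent LCA recount."""

import itertools
import random
from fractions import Fraction

import pytest

from pks3evo.reconcile import (
    CostScheme,
    format_event_table,
    lca_reconcile,
    reconcile_dl,
    reconcile_dtl,
    summarize_events,
)
from pks3evo.trees import parse_newick

from oracles import all_rooted_topologies, brute_force_dtl, random_topology


def _mapping(gene_tree):
    return {lab: lab.rsplit("_", 1)[0] for lab in gene_tree.leaf_labels()}


class TestWorkedInstances:
    def test_congruent_tree_costs_nothing(self, species_abc):
        g = parse_newick("((A_1,B_1),C_1);")
        r = reconcile_dtl(g, species_abc)
        assert (r.cost, r.duplications, r.transfers, r.losses) == (0.0, 0, 0, 0)
        assert r.codivergences == 2
        assert r.n_optimal == 1 and r.feasible

    def test_in_species_duplication(self, species_abc):
        g = parse_newick("(A_1,A_2);")
        r = reconcile_dl(g, species_abc)
        assert (r.cost, r.duplications, r.losses) == (1.5, 1, 0)

    def test_dl_on_discordant_triplet(self, species_abc):
        # brute-force enumeration for this instance gives 1 dup + 3 losses
        g = parse_newick("((A_1,C_1),B_1);")
        r = reconcile_dl(g, species_abc)
        assert (r.cost, r.duplications, r.losses) == (4.5, 1, 3)
        oracle_cost, oracle_count = brute_force_dtl(
            g, species_abc, _mapping(g), allow_transfer=False
        )
        assert Fraction(r.cost).limit_denominator() == oracle_cost
        assert r.n_optimal == oracle_count

    def test_cherry_prefers_loss_over_transfer(self, species_abc):
        g = parse_newick("(A_1,C_1);")
        r = reconcile_dtl(g, species_abc)
        assert r.cost == 1.0
        assert (r.transfers, r.losses) == (0, 1)
        assert r.n_optimal == 1

    def test_deep_shallow_cherry_takes_one_transfer(self, caterpillar9):
        g = parse_newick("(A_1,I_1);")
        r = reconcile_dtl(g, caterpillar9)
        assert r.cost == 6.0 and r.transfers == 1 and r.losses == 0
        dl = reconcile_dl(g, caterpillar9)
        assert dl.cost == 7.0

    def test_prohibitive_transfer_cost_reduces_to_dl(self, caterpillar9):
        g = parse_newick("((A_1,I_1),(C_1,F_1));")
        expensive = CostScheme(transfer=1000.0)
        dtl = reconcile_dtl(g, caterpillar9, costs=expensive)
        dl = reconcile_dl(g, caterpillar9, costs=expensive)
        assert dtl.cost == dl.cost
        assert dtl.duplications == dl.duplications
        assert dtl.losses == dl.losses
        assert dtl.n_optimal == dl.n_optimal

    def test_unmapped_leaf_is_named(self, species_abc):
        g = parse_newick("(A_1,ZZZ_9);")
        with pytest.raises(ValueError, match="ZZZ_9"):
            reconcile_dtl(g, species_abc)

    def test_cost_identity_of_canonical_solution(self, caterpillar9):
        rng = random.Random(5)
        species_labels = caterpillar9.leaf_labels()
        costs = CostScheme()
        for rep in range(20):
            leaves = [
                f"{rng.choice(species_labels)}_{i}" for i in range(rng.randint(2, 6))
            ]
            g = random_topology(leaves, rng)
            r = reconcile_dtl(g, caterpillar9, costs=costs)
            if not r.feasible:
                continue
            recomputed = (
                costs.codivergence * r.codivergences
                + costs.duplication * r.duplications
                + costs.transfer * r.transfers
                + costs.loss * r.losses
            )
            assert recomputed == pytest.approx(r.cost)


def _suite_instances():
    """Species topologies on 3-4 leaves x seeded random gene trees."""
    rng = random.Random(20260929)
    instances = []
    for labels in (["A", "B", "C"], ["A", "B", "C", "D"]):
        for sp in all_rooted_topologies(labels):
            for _ in range(4):
                k = rng.randint(2, 4)
                leaves = [f"{rng.choice(labels)}_{i}" for i in range(k)]
                instances.append((sp, random_topology(leaves, rng)))
    return instances


SUITE = _suite_instances()


class TestOracleEquivalence:
    @pytest.mark.parametrize("idx", range(0, len(SUITE), 1))
    def test_dp_matches_brute_force(self, idx):
        sp, g = SUITE[idx]
        sigma = _mapping(g)
        for allow_transfer in (True, False):
            got = reconcile_dtl(g, sp, allow_transfer=allow_transfer)
            want_cost, want_count = brute_force_dtl(
                g, sp, sigma, allow_transfer=allow_transfer
            )
            assert Fraction(got.cost).limit_denominator() == want_cost, (
                idx, allow_transfer)
            assert got.n_optimal == want_count, (idx, allow_transfer)

    def test_dp_matches_brute_force_on_larger_random_pairs(self):
        rng = random.Random(77)
        for rep in range(6):
            n = rng.choice([5, 6])
            labels = [chr(ord("A") + i) for i in range(n)]
            sp = random_topology(labels, rng)
            leaves = [
                f"{rng.choice(labels)}_{i}" for i in range(rng.randint(3, 5))
            ]
            g = random_topology(leaves, rng)
            got = reconcile_dtl(g, sp)
            want_cost, want_count = brute_force_dtl(g, sp, _mapping(g))
            assert Fraction(got.cost).limit_denominator() == want_cost
            assert got.n_optimal == want_count

    def test_unusual_costs_also_match(self):
        # a cost regime with cheap transfers and expensive losses
        costs = CostScheme(duplication=2.0, loss=3.0, transfer=1.0,
                           codivergence=0.5)
        frac = (Fraction(1, 2), Fraction(2), Fraction(1), Fraction(3))
        rng = random.Random(13)
        for sp, g in SUITE[::7]:
            got = reconcile_dtl(g, sp, costs=costs)
            want_cost, want_count = brute_force_dtl(
                g, sp, _mapping(g), costs=frac
            )
            assert Fraction(got.cost).limit_denominator() == want_cost
            assert got.n_optimal == want_count


class TestProperties:
    def test_limit_equivalence_on_suite(self):
        prohibitive = CostScheme(transfer=10_000.0)
        for sp, g in SUITE[::3]:
            dtl = reconcile_dtl(g, sp, costs=prohibitive)
            dl = reconcile_dl(g, sp, costs=prohibitive)
            assert dtl.cost == dl.cost
            assert (dtl.duplications, dtl.losses) == (dl.duplications, dl.losses)
            assert dtl.n_optimal == dl.n_optimal

    def test_cost_monotone_in_each_event_cost(self):
        base = CostScheme()
        bumps = [
            CostScheme(duplication=2.5),
            CostScheme(loss=2.0),
            CostScheme(transfer=7.0),
            CostScheme(codivergence=0.5),
        ]
        for sp, g in SUITE[::5]:
            c0 = reconcile_dtl(g, sp, costs=base).cost
            for costs in bumps:
                assert reconcile_dtl(g, sp, costs=costs).cost >= c0 - 1e-12

    def test_dl_duplications_equal_lca_recount(self):
        for sp, g in SUITE[::2]:
            r = reconcile_dl(g, sp)
            dups, losses = lca_reconcile(g, sp)
            assert r.duplications == dups
            assert r.losses == losses

    def test_solution_count_matches_enumeration_length(self, species_abc):
        # the count DP and the solution generator agree exactly
        from pks3evo.reconcile import _SpeciesIndex, _DP, CostScheme as CS

        rng = random.Random(23)
        sp = _SpeciesIndex(species_abc)
        for rep in range(30):
            leaves = [
                f"{rng.choice(['A', 'B', 'C'])}_{i}"
                for i in range(rng.randint(2, 4))
            ]
            g = random_topology(leaves, rng)
            sigma = {
                id(leaf): sp.leaf_of[leaf.label.rsplit('_', 1)[0]]
                for leaf in g.leaves()
            }
            dc, du, tc, lc, _ = CS().as_integers()
            dp = _DP(g, sp, sigma, (dc, du, tc, lc), True)
            assert dp.n_optimal() == len(list(dp.solutions()))


class TestPolytomies:
    def test_polytomy_resolves_to_congruent_topology(self):
        sp = parse_newick("(((A,B),C),D);")
        g = parse_newick("((A_1,B_1,C_1),D_1);")  # one degree-3 polytomy
        r = reconcile_dl(g, sp)
        assert r.cost == 0.0

    def test_polytomy_cost_equals_best_manual_resolution(self):
        sp = parse_newick("(((A,B),C),D);")
        g = parse_newick("(A_1,B_1,C_1,D_1);")
        r = reconcile_dtl(g, sp)
        # try every manual binary resolution through the binary code path
        shapes = [
            "((A_1,B_1),(C_1,D_1))", "(((A_1,B_1),C_1),D_1)",
            "(((A_1,C_1),B_1),D_1)", "(((C_1,D_1),A_1),B_1)",
            "((A_1,(B_1,C_1)),D_1)",
        ]
        best = min(
            reconcile_dtl(parse_newick(s + ";"), sp).cost for s in shapes
        )
        assert r.cost <= best
        assert r.cost == 0.0  # the caterpillar resolution is congruent

    def test_star_tree_reconciles(self, caterpillar9):
        # A..E are nested in the caterpillar: the star resolves to the
        # ladder, maps at the A..E ancestor and costs nothing
        g = parse_newick("(A_1,B_1,C_1,D_1,E_1);")
        r = reconcile_dl(g, caterpillar9)
        assert r.feasible and r.cost == 0.0
        assert r.codivergences == 4


class TestSummarize:
    def test_empty_input_gives_zero_table(self):
        import pandas as pd

        rows = pd.DataFrame(
            columns=["clade", "model", "duplications", "transfers",
                     "losses", "n_optimal", "feasible"]
        )
        out = summarize_events(rows)
        assert list(out["clade"]) == ["total"]
        assert out.iloc[0]["dtl_duplications"] is None

    def test_single_clade_passthrough(self):
        import pandas as pd

        rows = pd.DataFrame(
            [
                {"clade": "c1", "model": "DTL", "duplications": 3,
                 "transfers": 1, "losses": 7, "n_optimal": 4,
                 "feasible": True},
                {"clade": "c1", "model": "DL", "duplications": 5,
                 "transfers": 0, "losses": 9, "n_optimal": 1,
                 "feasible": True},
            ]
        )
        out = summarize_events(rows)
        row = out[out["clade"] == "c1"].iloc[0]
        assert (row["dtl_duplications"], row["dtl_transfers"],
                row["dtl_losses"], row["dtl_n_optimal"]) == (3, 1, 7, 4)
        assert (row["dl_duplications"], row["dl_losses"]) == (5, 9)

    def test_infeasible_clade_renders_as_dashes(self):
        import pandas as pd

        rows = pd.DataFrame(
            [
                {"clade": "c1", "model": "DTL", "duplications": 0,
                 "transfers": 0, "losses": 0, "n_optimal": 1,
                 "feasible": False},
                {"clade": "c1", "model": "DL", "duplications": 34,
                 "transfers": 0, "losses": 126, "n_optimal": 1,
                 "feasible": True},
            ]
        )
        formatted = format_event_table(summarize_events(rows))
        row = formatted[formatted["clade"] == "c1"].iloc[0]
        assert row["duplications"] == "-(34)"
        assert row["losses"] == "-(126)"
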