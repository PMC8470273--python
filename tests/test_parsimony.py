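"""Sankoff reconstruction: oracle equivalence, tie handling, branch events."""

import pytest

from karyoevo import (
    CostModel,
    PhyloTree,
    annotate_branch_events,
    brute_force_reconstruct,
    sankoff_reconstruct,
    tip_states_from_records,
    yule_tree,
)
from karyoevo.rearrangements import EventCount


def states_by_name(result):
    return {
        n.name: result.optimal_states[id(n)]
        for n in result.tree.postorder()
        if n.name is not None
    }


class TestPhyloTree:
    def test_newick_round_trip_with_flags(self):
        nwk = "((A,B)[&uncertain]X,('C c',D)Y)Root;"
        t = PhyloTree.from_newick(nwk)
        assert sorted(t.tip_labels()) == ["A", "B", "C c", "D"]
        x = t.find("X")
        assert x is not None and x.uncertain
        again = PhyloTree.from_newick(t.to_newick())
        assert again.find("X").uncertain
        assert sorted(again.tip_labels()) == sorted(t.tip_labels())

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PhyloTree.from_newick("((A,B),(A,C));")

    def test_collapse_uncertain_makes_polytomy(self):
        t = PhyloTree.from_newick("((A,B)[&uncertain]X,C)R;")
        collapsed = t.collapse_uncertain()
        assert len(collapsed.root.children) == 3

    def test_prune_tips_contracts_unary(self):
        t = PhyloTree.from_newick("((A,B)X,C)R;")
        pruned = t.prune_tips({"B"})
        assert sorted(pruned.tip_labels()) == ["A", "C"]
        assert len(pruned.root.children) == 2


class TestSankoff:
    def test_single_tip(self):
        t = PhyloTree.from_newick("A;")
        res = sankoff_reconstruct(t, {"A": 52})
        assert res.root_states == {52}
        assert res.total_cost == 0

    def test_three_tip_example(self):
        t = PhyloTree.from_newick("((A,B),C);")
        res = sankoff_reconstruct(t, {"A": 48, "B": 46, "C": 52})
        oracle = brute_force_reconstruct(t, {"A": 48, "B": 46, "C": 52})
        assert res.total_cost == 3
        assert res.total_cost == oracle.total_cost
        assert res.root_states == oracle.root_states

    def test_two_tip_cost(self):
        t = PhyloTree.from_newick("(A,B);")
        res = sankoff_reconstruct(t, {"A": 60, "B": 52})
        assert res.total_cost == 4

    def test_all_tips_equal_gives_zero_cost(self):
        t = PhyloTree.from_newick("((A,B),(C,(D,E)));")
        res = sankoff_reconstruct(t, {k: 54 for k in "ABCDE"})
        assert res.total_cost == 0
        for states in res.optimal_states.values():
            assert states == {54}

    def test_star_tree_tie_reported_as_set(self):
        t = PhyloTree.from_newick("(A,B)R;")
        res = sankoff_reconstruct(t, {"A": 50, "B": 54})
        assert res.root_states == {50, 52, 54}

    def test_oracle_equivalence_random_instances(self, rng):
        """Sankoff equals exhaustive enumeration on 200 random <=5-tip trees."""
        for _ in range(200):
            tree = yule_tree(int(rng.integers(2, 6)), rng)
            states = {
                l: int(rng.choice(range(40, 65, 2))) for l in tree.tip_labels()
            }
            a = sankoff_reconstruct(tree, states)
            b = brute_force_reconstruct(tree, states)
            assert a.total_cost == b.total_cost
            assert states_by_name(a) == states_by_name(b)

    def test_asymmetric_weights_match_oracle(self, rng):
        cm = CostModel(w_T=1.0, w_F=2.0)
        for _ in range(30):
            tree = yule_tree(4, rng)
            states = {l: int(rng.choice(range(40, 65, 2))) for l in tree.tip_labels()}
            a = sankoff_reconstruct(tree, states, cm)
            b = brute_force_reconstruct(tree, states, cm)
            assert a.total_cost == b.total_cost
            assert a.root_states == b.root_states

    def test_duplicating_a_tip_state_never_increases_cost(self, rng):
        base = PhyloTree.from_newick("((A,B),(C,D));")
        extended = PhyloTree.from_newick("((A,(B,B2)),(C,D));")
        for _ in range(25):
            states = {l: int(rng.choice(range(40, 65, 2))) for l in "ABCD"}
            more = dict(states, B2=states["B"])
            assert (
                sankoff_reconstruct(extended, more).total_cost
                <= sankoff_reconstruct(base, states).total_cost
            )

    def test_invariant_to_tip_order_and_polytomy_resolution(self):
        states = {"A": 44, "B": 60, "C": 52, "D": 56}
        shapes = [
            "((A,B),(C,D));",
            "((D,C),(B,A));",
            "(A,B,C,D);",
            "(C,(A,B,D));",
        ]
        costs = {}
        for s in shapes:
            costs[s] = sankoff_reconstruct(PhyloTree.from_newick(s), states).total_cost
        # same tips in any left-right order give identical costs
        assert costs["((A,B),(C,D));"] == costs["((D,C),(B,A));"]
        # a polytomy is never cheaper than its best resolution here
        assert costs["(A,B,C,D);"] >= costs["((A,B),(C,D));"]

    def test_missing_tips_pruned_with_warning(self, caplog):
        import logging

        t = PhyloTree.from_newick("((A,B),C);")
        with caplog.at_level(logging.WARNING, logger="karyoevo.parsimony"):
            res = sankoff_reconstruct(t, {"A": 50, "B": 52})
        assert res.pruned_tips == ("C",)
        assert "pruning" in caplog.text

    def test_state_outside_grid_rejected(self):
        t = PhyloTree.from_newick("(A,B);")
        with pytest.raises(ValueError, match="state set"):
            sankoff_reconstruct(t, {"A": 38, "B": 60})

    def test_brute_force_refuses_large_trees(self, rng):
        tree = yule_tree(12, rng)
        with pytest.raises(ValueError, match="internal nodes"):
            brute_force_reconstruct(
                tree, {l: 50 for l in tree.tip_labels()}
            )


class TestBranchEvents:
    def test_zero_cost_reconstruction_has_no_events(self):
        t = PhyloTree.from_newick("((A,B),C);")
        res = sankoff_reconstruct(t, {k: 60 for k in "ABC"})
        events = annotate_branch_events(res)
        assert all(e == EventCount() for e in events.values())

    def test_events_sum_to_total_cost(self, rng):
        from karyoevo import SimulationConfig, evolve_karyotypes

        for seed in range(100):
            sim = evolve_karyotypes(SimulationConfig(n_tips=6, seed=seed))
            states = {k: f.diploid_number for k, f in sim.tip_formulae.items()}
            res = sankoff_reconstruct(sim.tree, states)
            for policy in ("prefer-ancestral-max", "prefer-ancestral-min"):
                events = annotate_branch_events(res, policy)
                assert sum(e.total for e in events.values()) == res.total_cost

    def test_unknown_policy_rejected(self):
        t = PhyloTree.from_newick("(A,B);")
        res = sankoff_reconstruct(t, {"A": 60, "B": 52})
        with pytest.raises(ValueError, match="policy"):
            annotate_branch_events(res, "bogus")

    def test_all_optimal_covers_chosen_labelings(self):
        t = PhyloTree.from_newick("(A,B)R;")
        res = sankoff_reconstruct(t, {"A": 50, "B": 54})
        all_opt = annotate_branch_events(res, "all-optimal")
        res2 = sankoff_reconstruct(t, {"A": 50, "B": 54})
        chosen = annotate_branch_events(res2, "prefer-ancestral-max")
        for node_id, ec in chosen.items():
            assert ec in all_opt[node_id]


class TestFixtureReconstruction:
    def test_root_is_60(self, fixture_records, fixture_tree):
        states = tip_states_from_records(fixture_records, fixture_tree)
        res = sankoff_reconstruct(fixture_tree, states)
        assert res.root_states == {60}

    def test_hygromiid_geomitrid_ancestor_branch(self, fixture_records, fixture_tree):
        states = tip_states_from_records(fixture_records, fixture_tree)
        res = sankoff_reconstruct(fixture_tree, states)
        events = annotate_branch_events(res)
        node = res.tree.find("Hygromiidae-Geomitridae")
        assert events[id(node)] == EventCount(translocations=4)

    def test_collapsing_uncertain_branches_keeps_root(self, fixture_records, fixture_tree):
        states = tip_states_from_records(fixture_records, fixture_tree)
        res = sankoff_reconstruct(fixture_tree.collapse_uncertain(), states)
        assert 60 in res.root_states
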