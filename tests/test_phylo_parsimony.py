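"""Newick IO and linear-parsimony ancestral reconstruction."""

import numpy as np
import pytest

from domrep.phylo_parsimony import (
    assign_states,
    brute_force_parsimony,
    parse_newick,
    reconstruct_character,
    sankoff_linear,
    wagner_down_pass,
    write_newick,
)
from domrep.synthetic_data import simulate_yule_tree
from .conftest import random_binary_tree


class TestNewick:
    def test_cherry_with_lengths(self):
        t = parse_newick("(A:1,B:1);")
        labels = {n.label: n for n in t.preorder()}
        assert set(labels) == {"n2", "A", "B"}
        assert labels["A"].branch_length == 1

    def test_internal_labels_preserved(self):
        t = parse_newick("((A,B)n3,C)n2;")
        assert {n.label for n in t.preorder() if not n.is_leaf} == {"n2", "n3"}

    def test_autonaming_preorder(self):
        t = parse_newick("((A,B),(C,D));")
        internals = [n.label for n in t.preorder() if not n.is_leaf]
        assert internals == ["n2", "n3", "n4"]

    def test_single_leaf(self):
        t = parse_newick("A;")
        assert t.root.label == "A" and t.root.is_leaf

    def test_multifurcation_allowed(self):
        t = parse_newick("(A,B,C);")
        assert len(t.root.children) == 3 and not t.is_binary()

    @pytest.mark.parametrize("bad", ["", "   ", "((A,B);", "(A,B))C;", "(A,A);"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_newick(bad)

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_on_simulated_trees(self, seed):
        t = simulate_yule_tree(int(np.random.default_rng(seed).integers(2, 30)), 1.0, seed)
        s = write_newick(t)
        back = parse_newick(s)
        assert write_newick(back) == s
        a = {n.label: n.branch_length for n in t.preorder()}
        b = {n.label: n.branch_length for n in back.preorder()}
        assert a == b


def random_states(t, rng, max_state=4):
    return {leaf.label: int(rng.integers(0, max_state + 1)) for leaf in t.leaves()}


class TestWagnerDownPass:
    def test_constant_cherry(self):
        t = parse_newick("(A,B);")
        intervals, cost = wagner_down_pass(t, {"A": 0, "B": 0})
        assert cost == 0 and (intervals["n2"].lo, intervals["n2"].hi) == (0, 0)

    def test_divergent_cherry_interval_and_cost(self):
        t = parse_newick("(A,B);")
        intervals, cost = wagner_down_pass(t, {"A": 0, "B": 2})
        assert cost == 2 and (intervals["n2"].lo, intervals["n2"].hi) == (0, 2)

    def test_four_leaf_balanced(self, balanced4):
        _, cost = wagner_down_pass(balanced4, {"A": 0, "B": 1, "C": 4, "D": 4})
        assert cost == 4 == brute_force_parsimony(balanced4, {"A": 0, "B": 1, "C": 4, "D": 4})

    def test_nonbinary_rejected(self):
        t = parse_newick("(A,B,C);")
        with pytest.raises(ValueError, match="binary"):
            wagner_down_pass(t, {"A": 0, "B": 1, "C": 2})

    def test_missing_leaf_state_rejected(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError, match="missing"):
            wagner_down_pass(t, {"A": 0})


class TestSankoffLinear:
    def test_star_tree_median_closed_form(self):
        t = parse_newick("(A,B,C);")
        _, cost = sankoff_linear(t, {"A": 0, "B": 1, "C": 5})
        assert cost == 5  # sum |leaf - median|

    def test_constant_leaves_zero_cost(self):
        t = parse_newick("((A,B),(C,D));")
        vecs, cost = sankoff_linear(t, {k: 3 for k in "ABCD"})
        assert cost == 0 and vecs["n2"][3] == 0

    def test_max_state_below_leaves_rejected(self):
        t = parse_newick("(A,B);")
        with pytest.raises(ValueError, match="max_state"):
            sankoff_linear(t, {"A": 0, "B": 5}, max_state=3)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_wagner_and_brute_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        t = random_binary_tree(int(rng.integers(2, 7)), rng)
        x = random_states(t, rng)
        _, cs = sankoff_linear(t, x)
        _, cw = wagner_down_pass(t, x)
        assert cs == cw == brute_force_parsimony(t, x)

    def test_widening_state_range_does_not_change_cost(self):
        rng = np.random.default_rng(4)
        t = random_binary_tree(6, rng)
        x = random_states(t, rng)
        assert sankoff_linear(t, x)[1] == sankoff_linear(t, x, max_state=12)[1]


class TestAssignStates:
    def test_cherry_root_takes_smallest_optimal(self):
        t = parse_newick("(A,B);")
        vecs, _ = sankoff_linear(t, {"A": 0, "B": 2})
        a = assign_states(t, vecs)
        assert a.state["n2"] == 0 and a.cost == 2

    def test_root_largest_policy(self):
        t = parse_newick("(A,B);")
        vecs, _ = sankoff_linear(t, {"A": 0, "B": 2})
        assert assign_states(t, vecs, policy="root-largest").state["n2"] == 2

    def test_constant_leaves_constant_assignment(self):
        t = parse_newick("((A,B),(C,D));")
        a = reconstruct_character(t, {k: 2 for k in "ABCD"})
        assert set(a.state.values()) == {2} and a.cost == 0

    @pytest.mark.parametrize("seed", range(200))
    def test_realized_cost_equals_dp_minimum(self, seed):
        rng = np.random.default_rng(1000 + seed)
        t = random_binary_tree(int(rng.integers(2, 12)), rng)
        x = random_states(t, rng, max_state=6)
        vecs, cost = sankoff_linear(t, x)
        a = assign_states(t, vecs)
        assert a.cost == cost
        assert all(a.state[leaf.label] == x[leaf.label] for leaf in t.leaves())

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        t = random_binary_tree(9, rng)
        x = random_states(t, rng)
        a1 = reconstruct_character(t, x)
        a2 = reconstruct_character(t, x)
        assert a1.state == a2.state and a1.cost == a2.cost


class TestParsimonyProperties:
    @pytest.mark.parametrize("seed", range(30))
    def test_cost_at_least_leaf_range(self, seed):
        rng = np.random.default_rng(seed)
        t = random_binary_tree(int(rng.integers(2, 10)), rng)
        x = random_states(t, rng, max_state=8)
        _, cost = sankoff_linear(t, x)
        assert cost >= max(x.values()) - min(x.values())

    def test_two_leaf_equality(self):
        t = parse_newick("(A,B);")
        _, cost = sankoff_linear(t, {"A": 1, "B": 7})
        assert cost == 6

    def test_branch_lengths_never_affect_result(self):
        a = parse_newick("((A:1,B:2)n3:0.5,(C:9,D:0.1)n4:3)n2;")
        b = parse_newick("((A,B)n3,(C,D)n4)n2;")
        x = {"A": 0, "B": 3, "C": 1, "D": 2}
        assert sankoff_linear(a, x)[1] == sankoff_linear(b, x)[1]
        ra = reconstruct_character(a, x)
        rb = reconstruct_character(b, x)
        assert ra.state == rb.state

    def test_optimal_root_within_leaf_range(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            t = random_binary_tree(int(rng.integers(2, 8)), rng)
            x = random_states(t, rng)
            vecs, cost = sankoff_linear(t, x, max_state=max(x.values()) + 5)
            optimal = np.flatnonzero(vecs[t.root.label] == cost)
            assert optimal.min() >= min(x.values()) and optimal.max() <= max(x.values())


class TestBruteForce:
    def test_single_branch_and_constant_cherry(self):
        assert brute_force_parsimony(parse_newick("(A,B);"), {"A": 1, "B": 1}) == 0

    def test_guard_on_large_trees(self):
        rng = np.random.default_rng(0)
        t = random_binary_tree(12, rng)
        with pytest.raises(ValueError, match="brute force"):
            brute_force_parsimony(t, random_states(t, rng))
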