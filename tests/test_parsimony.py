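"""Dollo presence, ACCTRAN grades, combined reconstruction, antler assembly.

Expected values for the worked examples were first computed with the
brute-force enumerations in ``oracles.py`` and then frozen here; the
exhaustive comparisons themselves live in the acceptance suite.
"""

from itertools import product

import pytest

from antlerevo.parsimony import (acctran_refine, assemble_ancestral_antler,
                                 count_points, dollo_presence,
                                 reconstruct_character)
from antlerevo.trees import Tree

from oracles import (change_edges, min_single_gain_losses,
                     minimal_grade_assignments, rooted_shapes, shape_to_tree)


def tree(newick):
    return Tree.from_newick(newick)


class TestDolloPresence:
    def test_all_present(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        presence, gain, losses = dollo_presence(
            t, {l: True for l in "ABCD"})
        assert gain == "r" and losses == set()
        assert all(presence.values())

    def test_single_present_tip(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        presence, gain, losses = dollo_presence(
            t, {"A": True, "B": False, "C": False, "D": False})
        assert gain == "A" and losses == set()
        assert [l for l, p in presence.items() if p] == ["A"]

    def test_two_losses_unique_minimum(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        tips = {"A": True, "B": False, "C": True, "D": False}
        presence, gain, losses = dollo_presence(t, tips)
        assert gain == "r" and losses == {"B", "D"}
        best, n_minimal = min_single_gain_losses(t, tips)
        assert best == len(losses) == 2
        assert n_minimal == 1

    def test_no_present_tips(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        presence, gain, losses = dollo_presence(
            t, {l: False for l in "ABCD"})
        assert gain is None and losses == set()
        assert not any(presence.values())

    def test_unlabelled_leaf_rejected(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        with pytest.raises(ValueError, match="unlabelled"):
            dollo_presence(t, {"A": True})

    def test_gain_inside_one_clade(self):
        t = tree("(((A,B)ab,C)abc,(D,E)de)r;")
        _, gain, losses = dollo_presence(
            t, {"A": True, "B": True, "C": False, "D": False, "E": False})
        assert gain == "ab" and losses == set()


class TestAcctran:
    def test_all_grade_two(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        grades = acctran_refine(t, {l: 2 for l in "ABCD"})
        assert set(grades.values()) == {2}

    def test_single_demotion_on_terminal_edge(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        grades = acctran_refine(t, {"A": 2, "B": 1, "C": 2, "D": 2})
        assert grades == {"r": 2, "ab": 2, "A": 2, "B": 1,
                          "cd": 2, "C": 2, "D": 2}
        assert change_edges(t, grades) == {"B"}

    def test_root_ambiguity_resolves_to_two(self):
        t = tree("(A,(B,(C,D)cd)bcd)r;")
        grades = acctran_refine(t, {"A": 2, "B": 1, "C": 2, "D": 1})
        assert grades["r"] == 2
        assert change_edges(t, grades) == {"bcd", "C"}

    def test_ungraded_tip_rejected(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        with pytest.raises(ValueError, match="ungraded"):
            acctran_refine(t, {"A": 2, "B": 1, "C": 2})

    def test_matches_fitch_length_on_small_trees(self):
        # spot-check against the exhaustive oracle on one 5-leaf shape
        t = tree("(((A,B)ab,C)abc,(D,E)de)r;")
        for grades in product([1, 2], repeat=5):
            tips = dict(zip("ABCDE", grades))
            mine = acctran_refine(t, tips)
            best, _ = minimal_grade_assignments(t, tips)
            assert len(change_edges(t, mine)) == best


class TestReconstructCharacter:
    def test_combined_example(self):
        t = tree("(((A,B)ab,C)abc,(D,E)de)r;")
        result = reconstruct_character(
            t, {"A": 2, "B": 2, "C": 0, "D": 1, "E": 0}, "x")
        assert result.gain_edge == "r"
        assert result.loss_edges == {"C", "E"}
        assert result.node_states["r"] == 2
        # the 2->1 demotion sits on the merged edge toward D (its rootward
        # half once the state-0 tip E is pruned)
        assert result.grade_change_edges == {"de"}
        assert result.node_states["D"] == 1

    def test_all_absent(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        result = reconstruct_character(t, {l: 0 for l in "ABCD"})
        assert result.gain_edge is None
        assert set(result.node_states.values()) == {0}

    def test_all_grade_two(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        result = reconstruct_character(t, {l: 2 for l in "ABCD"})
        assert result.gain_edge == "r"
        assert not result.loss_edges and not result.grade_change_edges
        assert set(result.node_states.values()) == {2}

    def test_singleton_state_one(self):
        # a character present in one species at grade 1 gains on its
        # terminal edge at grade 1
        t = tree("((A,B)ab,(C,D)cd)r;")
        result = reconstruct_character(
            t, {"A": 1, "B": 0, "C": 0, "D": 0})
        assert result.gain_edge == "A"
        assert result.node_states["A"] == 1

    def test_idempotent_on_tip_readback(self):
        t = tree("(((A,B)ab,C)abc,(D,E)de)r;")
        tips = {"A": 2, "B": 1, "C": 0, "D": 2, "E": 0}
        first = reconstruct_character(t, tips)
        readback = {l: first.node_states[l] for l in "ABCDE"}
        second = reconstruct_character(t, readback)
        assert first.node_states == second.node_states
        assert first.gain_edge == second.gain_edge
        assert first.loss_edges == second.loss_edges

    def test_missing_tip_rejected(self):
        t = tree("((A,B)ab,(C,D)cd)r;")
        with pytest.raises(ValueError, match="coded"):
            reconstruct_character(t, {"A": 2, "B": 1, "C": 2})


class TestAssembly:
    def test_root_antler_two_pointed(self, registry, fitted):
        antler = fitted.ancestral_antler("Cervidae")
        assert antler.elements == {"B", "L"}
        assert antler.point_count == 2

    def test_cervini_mrca(self, registry, fitted):
        antler = fitted.ancestral_antler("Cervini")
        assert {"B", "L", "T", "H", "BWP"} <= antler.elements
        assert antler.point_count == 3

    def test_capreolinae_mrca(self, registry, fitted):
        antler = fitted.ancestral_antler("Capreolinae")
        assert {"B", "L", "F", "U"} <= antler.elements
        assert antler.point_count == 3

    def test_empty_antler(self, registry, fitted):
        from antlerevo.parsimony import AncestralAntler

        empty = AncestralAntler("x", {}, "", 0)
        assert count_points(empty, registry) == 0

    def test_dependency_violation_reported(self, registry):
        from antlerevo.parsimony import ReconstructionResult

        fake = {
            "T": ReconstructionResult("T", {"n": 2}, "n", set(), set()),
        }
        antler = assemble_ancestral_antler("n", fake, registry)
        # trez tine without its lower beam: excluded and flagged
        assert antler.elements == set()
        assert any("requires" in v for v in antler.dependency_violations)

    def test_point_count_examples(self, registry):
        from antlerevo.parsimony import AncestralAntler

        two = AncestralAntler("x", {"B": 2, "L": 2}, "", 0)
        assert count_points(two, registry) == 2
        three = AncestralAntler("x", {"B": 2, "L": 2, "F": 2, "U": 2}, "", 0)
        assert count_points(three, registry) == 3

    def test_independent_origins_of_three_pointed_forms(self, fitted):
        trez = fitted.reconstruction("T")
        frontal = fitted.reconstruction("F")
        assert trez.gain_edge == "Cervini"
        assert frontal.gain_edge == "Capreolinae"
        assert trez.gain_edge != frontal.gain_edge


class TestDolloInvariants:
    def test_at_most_one_gain_and_no_regain(self, fitted):
        tree = fitted.tree
        for element in fitted.elements:
            result = fitted.reconstruction(element)
            gains = 0
            for node in tree.preorder():
                state = result.node_states[node.label]
                parent_state = (0 if node.parent is None
                                else result.node_states[node.parent.label])
                if parent_state == 0 and state > 0:
                    gains += 1
            assert gains <= 1, element

    def test_tip_states_preserved(self, fitted):
        states = fitted.model.char_matrix.states
        for element in fitted.elements:
            result = fitted.reconstruction(element)
            for leaf in fitted.tree.leaf_labels():
                assert result.node_states[leaf] == states.loc[leaf, element]


def test_shape_enumeration_counts():
    # Wedderburn-Etherington numbers for 2..6 leaves
    assert [len(rooted_shapes(n)) for n in range(2, 7)] == [1, 1, 2, 3, 6]
    t = shape_to_tree(rooted_shapes(4)[0])
    assert len(t.leaf_labels()) == 4
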