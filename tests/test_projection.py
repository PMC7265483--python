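"""Burr-projection geometry: arc primitives, chains, zones, rendering."""

import xml.etree.ElementTree as ET

import pytest
from hypothesis import given
from hypothesis import strategies as st

from antlerevo.projection import (Fork, TineNode, TineTree, build_diagram,
                                  compute_zones, delete_tine,
                                  inverse_remap_across_tine, opposite_point,
                                  project_fork, project_to_burr,
                                  remap_across_tine, render_diagram)
from antlerevo.synthetic import SimulationConfig, mirrored_pair, synthetic_antler

positions = st.floats(0.0, 359.999, allow_nan=False)
circumferences = st.floats(0.5, 100.0, allow_nan=False, exclude_min=True)


class TestOppositePoint:
    @pytest.mark.parametrize("ridge,C,expected", [
        (0.0, 12.0, 6.0),
        (9.0, 12.0, 3.0),
        (0.0, 2.0, 1.0),
    ])
    def test_examples(self, ridge, C, expected):
        assert opposite_point(ridge, C) == pytest.approx(expected)

    @given(st.floats(0, 99.9), circumferences)
    def test_involution(self, ridge, C):
        ridge = ridge % C
        twice = opposite_point(opposite_point(ridge, C), C)
        assert twice == pytest.approx(ridge, abs=1e-9)

    def test_bad_circumference(self):
        with pytest.raises(ValueError):
            opposite_point(1.0, 0.0)


class TestRemapAcrossTine:
    def test_ridge_maps_to_opposite(self):
        assert remap_across_tine(1.0, 1.0, 5.0, 12.0) == pytest.approx(
            opposite_point(1.0, 12.0))

    def test_boundary_fixed_point(self):
        assert remap_across_tine(5.0, 1.0, 5.0, 12.0) == pytest.approx(5.0)

    def test_midpoint_example(self):
        # x = y, arc(opposite -> boundary) = 6: midpoint maps X = 3 from opposite
        C, ridge = 24.0, 0.0
        boundary = 18.0  # -arc ridge->boundary length 6; opposite at 12
        alpha = 21.0  # midpoint of the -arc
        out = remap_across_tine(alpha, ridge, boundary, C)
        # target arc runs opposite(12) -> boundary(18) in + direction, length 6
        assert out == pytest.approx(15.0)

    def test_degenerate_interval(self):
        assert remap_across_tine(3.0, 3.0, 3.0, 10.0) == pytest.approx(3.0)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_strictly_monotone(self, f1, f2):
        C, ridge, boundary = 36.0, 2.0, 14.0
        if abs(f1 - f2) < 1e-6:
            return
        lo, hi = sorted([f1, f2])
        opp = opposite_point(ridge, C)
        d_lo = (opp - remap_across_tine(ridge + lo * (boundary - ridge),
                                        ridge, boundary, C)) % C
        d_hi = (opp - remap_across_tine(ridge + hi * (boundary - ridge),
                                        ridge, boundary, C)) % C
        # images advance strictly from the opposite point toward the boundary
        assert d_lo < d_hi

    @given(st.floats(0.0, 1.0))
    def test_round_trip(self, frac):
        C, ridge, boundary = 17.0, 3.0, 11.0
        alpha = ridge + frac * (boundary - ridge)
        out = remap_across_tine(alpha, ridge, boundary, C)
        back = inverse_remap_across_tine(out, ridge, boundary, C)
        assert back == pytest.approx(alpha, abs=1e-9)


def two_pointed(boundary=0.5):
    root = TineNode("base", "beam", 5, 2, 10, Fork(0.0, boundary), [
        TineNode("B", "tine", 20, 3, 9),
        TineNode("L", "beam", 30, 4, 12),
    ])
    return TineTree(root, skull_marks={"SR": 15.0, "TR": 130.0, "BN": 200.0})


def nippon_like():
    """Fixture mimicking the classic four-pointed structure
    (brow tine, lower beam, trez tine, higher beam, two crown tines)."""
    crown = TineNode("H", "beam", 25, 3, 8, Fork(0.3, 0.7), [
        TineNode("CI", "tine", 15, 2, 5),
        TineNode("CO", "tine", 14, 2, 5),
    ])
    lower = TineNode("L", "beam", 40, 5, 14, Fork(0.25, 0.6), [
        TineNode("T", "tine", 22, 3, 8),
        crown,
    ])
    root = TineNode("base", "beam", 4, 5, 16, Fork(0.0, 0.42), [
        TineNode("B", "tine", 25, 4, 10),
        lower,
    ])
    return TineTree(root, skull_marks={"SR": 15.0, "TR": 130.0, "BN": 200.0})


class TestProjectionChain:
    def test_first_fork_no_intervening_tines(self):
        tree = two_pointed(0.5)
        # opposite point of the crotch on the child circle maps to the window
        # midpoint: B's window is [0, 0.5] -> 90 deg
        assert project_to_burr(tree, "B") == pytest.approx(90.0)
        assert project_to_burr(tree, "L") == pytest.approx(270.0)

    def test_two_fork_hand_computed(self):
        # hand-composed chain on the explicit geometry of nippon_like():
        # T lives in the window [0.25, 0.6] of L, whose own region is
        # [0.42, 1.0); T's direction = 0.42 + (0.25 + 0.5*0.35)*0.58
        tree = nippon_like()
        l_start, l_len = 0.42, 0.58
        t_mid = 0.25 + 0.5 * (0.6 - 0.25)
        assert project_to_burr(tree, "T") == pytest.approx(
            (l_start + t_mid * l_len) * 360.0)
        # fork T/H marks: images of 0.25 and 0.6
        lat, med = project_fork(tree, "T/H")
        assert lat == pytest.approx((l_start + 0.25 * l_len) * 360.0)
        assert med == pytest.approx((l_start + 0.6 * l_len) * 360.0)

    def test_unknown_element(self):
        with pytest.raises(KeyError):
            project_to_burr(two_pointed(), "Z")
        with pytest.raises(KeyError):
            project_fork(two_pointed(), "X/Y")


class TestZones:
    def test_two_pointed_partition(self):
        zones = compute_zones(two_pointed(0.5))
        assert set(zones) == {"B", "L"}
        assert zones["B"] == [(0.0, 180.0)]
        assert zones["L"] == [(180.0, 360.0)]

    def test_three_element_boundaries_are_marks(self):
        # base -> (A, stem(B, C)): four projected marks bound three zones
        stem = TineNode("S", "beam", 30, 4, 12, Fork(0.3, 0.6), [
            TineNode("Bt", "tine", 20, 3, 9),
            TineNode("Ct", "tine", 20, 3, 9),
        ])
        root = TineNode("base", "beam", 5, 4, 12, Fork(0.0, 0.4), [
            TineNode("A", "tine", 20, 3, 9), stem])
        tree = TineTree(root)
        diagram = build_diagram(tree)
        marks = sorted({round(a, 6) for pair in diagram.fork_positions.values()
                        for a in pair})
        boundaries = sorted({round(b, 6) for arcs in diagram.zones.values()
                             for arc in arcs for b in arc if b not in (360.0,)})
        assert len(diagram.zones) == 4  # A, S, Bt, Ct
        assert set(marks) <= set(boundaries) | {360.0}

    @pytest.mark.parametrize("seed", range(12))
    def test_random_partition_and_membership(self, seed):
        tree = synthetic_antler(SimulationConfig(seed=seed), depth=3)
        diagram = build_diagram(tree)
        diagram.validate()  # partition + direction-in-own-zone
        total = sum(hi - lo for arcs in diagram.zones.values()
                    for lo, hi in arcs)
        assert total == pytest.approx(360.0)


class TestBuildDiagram:
    def test_hierarchy_pattern(self):
        diagram = build_diagram(nippon_like())
        assert diagram.hierarchy == "(B,L(T,H(CI,CO)))"

    def test_single_spike(self):
        tree = TineTree(TineNode("L", "beam", 30, 4, 12))
        diagram = build_diagram(tree)
        assert diagram.fork_positions == {}
        assert set(diagram.zones) == {"L"}
        assert diagram.zones["L"] == [(0.0, 360.0)]

    def test_empty_antler(self):
        tree = TineTree(TineNode("base", "beam", 1, 1, 1))
        diagram = build_diagram(tree)
        assert diagram.branching_directions == {}
        assert diagram.zones == {}

    def test_mirrored_pair_equal(self):
        left, right = mirrored_pair(SimulationConfig(seed=11), depth=2)
        dl, dr = build_diagram(left), build_diagram(right)
        assert dl.branching_directions == dr.branching_directions
        assert dl.zones == dr.zones
        assert dl.fork_positions == dr.fork_positions

    def test_json_round_trip(self):
        tree = nippon_like()
        again = TineTree.from_json(tree.to_json())
        assert build_diagram(again).branching_directions == pytest.approx(
            build_diagram(tree).branching_directions)


class TestDeletionInvariance:
    @pytest.mark.parametrize("seed", range(8))
    def test_distal_projections_unchanged(self, seed):
        tree = synthetic_antler(SimulationConfig(seed=seed), depth=3)
        target = None
        for node in tree.walk():
            if (node.children and tree.parent(node) is not None
                    and node.children[0].is_leaf):
                target, sibling = node.children[0], node.children[1]
                break
        if target is None:
            pytest.skip("no deletable window tine in this geometry")
        distal = [n.code for n in _walk(sibling) if n is not sibling]
        before = {e: project_to_burr(tree, e) for e in distal}
        pruned = delete_tine(tree, target.code)
        for element in distal:
            assert project_to_burr(pruned, element) == pytest.approx(
                before[element], abs=1e-9)

    def test_first_fork_not_deletable(self):
        with pytest.raises(ValueError):
            delete_tine(two_pointed(), "B")


def _walk(node):
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


class TestValidation:
    def test_fork_window_must_not_wrap(self):
        with pytest.raises(ValueError):
            TineTree(TineNode("base", "beam", 1, 1, 1, Fork(0.0, 1.2), [
                TineNode("A"), TineNode("B")]))

    def test_root_ridge_anchors_origin(self):
        with pytest.raises(ValueError):
            TineTree(TineNode("base", "beam", 1, 1, 1, Fork(0.1, 0.5), [
                TineNode("A"), TineNode("B")]))

    def test_positive_dimensions(self):
        with pytest.raises(ValueError):
            TineTree(TineNode("L", "beam", -3, 1, 1))

    def test_forks_bifurcate(self):
        with pytest.raises(ValueError):
            TineTree(TineNode("base", "beam", 1, 1, 1, Fork(0.0, 0.5),
                              [TineNode("A")]))


class TestRender:
    @pytest.mark.parametrize("seed", [0, 3])
    def test_well_formed_svg_with_counts(self, seed):
        tree = synthetic_antler(SimulationConfig(seed=seed), depth=2)
        diagram = build_diagram(tree)
        svg = render_diagram(diagram)
        root = ET.fromstring(svg)
        ns = "{http://www.w3.org/2000/svg}"
        dots = [e for e in root.iter(f"{ns}circle")
                if e.get("class", "").startswith("dot")]
        sectors = [e for e in root.iter(f"{ns}path")
                   if e.get("class", "").startswith("zone")]
        n = len(diagram.elements())
        assert len(dots) == n
        assert len({e.get("class").split()[0].replace("zone zone-", "")
                    for e in sectors}) <= n
        zone_codes = {e.get("class").split("zone-")[1] for e in sectors}
        assert zone_codes == set(code for code, arcs in diagram.zones.items()
                                 if arcs)

    def test_empty_antler_renders_circle_only(self):
        tree = TineTree(TineNode("base", "beam", 1, 1, 1))
        svg = render_diagram(build_diagram(tree))
        root = ET.fromstring(svg)
        assert not [e for e in root.iter() if "dot" in (e.get("class") or "")]
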