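"""Hybrid Dollo + ACCTRAN ancestral-state reconstruction on a fixed topology.

Each antler element is a three-state character per species: 0 (never
observed), 1 (observed in under 80% of adult antlers), 2 (at least 80%).
Reconstruction is layered:

* presence (0 versus {1, 2}) follows Dollo parsimony — a structurally
  complex element arises exactly once and may be lost any number of times.
  With a single permitted gain the optimum is forced: the gain sits on the
  stem edge of the MRCA of all present tips, a node inside that clade is
  present iff its subtree retains a present tip, and the losses are the stem
  edges of the maximal all-absent subtrees.  This placement attains the
  minimum loss count among single-gain histories, uniquely.

* grade (1 versus 2) is Fitch parsimony over the present region with
  ACCTRAN resolution: state changes are pulled as close to the root of the
  present region as possible, and a residual root ambiguity resolves to
  grade 2 (a newly gained adaptive element is expected to fix in the
  population immediately after its gain, so 0 -> 1 -> 2 happens promptly;
  2 -> 1 demotions occur independently later).

Edges are named by their child node; the root's stem edge is the root label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .registry import Registry
from .trees import Tree, TreeNode

__all__ = [
    "ReconstructionResult",
    "AncestralAntler",
    "dollo_presence",
    "acctran_refine",
    "reconstruct_character",
    "assemble_ancestral_antler",
    "count_points",
]


# ---------------------------------------------------------------------------
# Dollo presence layer
# ---------------------------------------------------------------------------

def dollo_presence(tree: Tree, tip_present: dict[str, bool]
                   ) -> tuple[dict[str, bool], str | None, set[str]]:
    """Single-gain presence reconstruction.

    Returns ``(node_presence, gain_edge, loss_edges)``.  ``gain_edge`` is the
    stem edge of the MRCA of the present tips (``None`` when no tip is
    present); ``loss_edges`` are the stem edges of the maximal absent
    subtrees inside the present clade.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in tip_present]
    if missing:
        raise ValueError(f"unlabelled leaves: {missing}")
    present_tips = [l for l in leaves if tip_present[l]]
    presence = {n.label: False for n in tree.preorder()}
    if not present_tips:
        return presence, None, set()
    mrca = tree.mrca(present_tips)

    has_tip: dict[str, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            has_tip[node.label] = tip_present[node.label]
        else:
            has_tip[node.label] = any(has_tip[c.label] for c in node.children)

    in_clade = tree.subtree_labels(mrca.label)
    for label in in_clade:
        presence[label] = has_tip[label]

    losses = {
        node.label
        for node in tree.preorder()
        if node.label in in_clade and not presence[node.label]
        and node.parent is not None and presence.get(node.parent.label, False)
    }
    return presence, mrca.label, losses


# ---------------------------------------------------------------------------
# ACCTRAN grade layer
# ---------------------------------------------------------------------------

def acctran_refine(tree: Tree, tip_grades: dict[str, int],
                   region: set[str] | None = None,
                   region_root: str | None = None) -> dict[str, int]:
    """Fitch parsimony over {1, 2} with ACCTRAN resolution.

    ``region`` restricts the pass to the present part of the tree (nodes
    outside it are ignored; a node with a single in-region child passes that
    child's state set through).  Tips of the region must all be graded.
    Root-state ambiguity resolves to 2.
    """
    if region is None:
        region = {n.label for n in tree.preorder()}
    root = tree.node(region_root) if region_root else tree.root
    prelim: dict[str, set[int]] = {}

    def up(node: TreeNode) -> set[int]:
        kids = [c for c in node.children if c.label in region]
        if not kids:
            grade = tip_grades.get(node.label)
            if grade not in (1, 2):
                raise ValueError(f"ungraded region tip {node.label!r}")
            s = {grade}
        else:
            sets = [up(c) for c in kids]
            s = set.intersection(*sets) or set.union(*sets)
        prelim[node.label] = s
        return s

    up(root)
    final: dict[str, int] = {}

    def down(node: TreeNode, parent_state: int | None) -> None:
        s = prelim[node.label]
        if parent_state is not None and parent_state in s:
            state = parent_state
        elif len(s) == 1:
            state = next(iter(s))
        else:
            state = 2  # residual ambiguity: accelerate the 1 -> 2 gain
        final[node.label] = state
        for child in node.children:
            if child.label in region:
                down(child, state)

    down(root, None)
    return final


# ---------------------------------------------------------------------------
# combined reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionResult:
    """Per-node states and edge events for one element on the fixed tree."""

    element: str
    node_states: dict[str, int]
    gain_edge: str | None
    loss_edges: set[str]
    grade_change_edges: set[str]

    def events_table(self) -> list[tuple[str, str]]:
        rows = []
        if self.gain_edge is not None:
            rows.append((self.gain_edge, "gain"))
        rows += [(e, "loss") for e in sorted(self.loss_edges)]
        rows += [(e, "grade_change") for e in sorted(self.grade_change_edges)]
        return rows

    def state_at(self, node_label: str) -> int:
        return self.node_states[node_label]


def reconstruct_character(tree: Tree, coded_tips: dict[str, int],
                          element: str = "") -> ReconstructionResult:
    """Two-layer reconstruction of one element.

    Presence by Dollo on state > 0; grades by the ACCTRAN pass over the
    present region with state-0 tips pruned (their stem edges are losses);
    everything outside the present region is state 0.
    """
    leaves = tree.leaf_labels()
    missing = [l for l in leaves if l not in coded_tips]
    if missing:
        raise ValueError(f"tips without coded states: {missing}")
    bad = {l: s for l, s in coded_tips.items() if s not in (0, 1, 2)}
    if bad:
        raise ValueError(f"invalid character states: {bad}")

    tip_present = {l: coded_tips[l] > 0 for l in leaves}
    presence, gain_edge, losses = dollo_presence(tree, tip_present)
    states = {label: 0 for label in presence}
    grade_changes: set[str] = set()
    if gain_edge is not None:
        region = {label for label, p in presence.items() if p}
        tip_grades = {l: coded_tips[l] for l in leaves if coded_tips[l] > 0}
        grades = acctran_refine(tree, tip_grades, region=region,
                                region_root=gain_edge)
        states.update(grades)
        for label in region:
            node = tree.node(label)
            if node.parent is not None and node.parent.label in region:
                if grades[label] != grades[node.parent.label]:
                    grade_changes.add(label)
    return ReconstructionResult(element, states, gain_edge, losses, grade_changes)


# ---------------------------------------------------------------------------
# ancestral antler assembly
# ---------------------------------------------------------------------------

@dataclass
class AncestralAntler:
    """Assembled element set of one ancestral node, with its point count."""

    node: str
    element_states: dict[str, int]
    skeleton: str
    point_count: int
    dependency_violations: list[str] = field(default_factory=list)

    @property
    def elements(self) -> set[str]:
        return set(self.element_states)


def assemble_ancestral_antler(node_label: str,
                              reconstructions: dict[str, ReconstructionResult],
                              registry: Registry) -> AncestralAntler:
    """Collect the elements reconstructed as present at one node.

    An element is placed on the antler iff its state exceeds 0 at the node
    and all structurally required elements are present too; violations are
    reported, never silently repaired.
    """
    raw = {
        element: result.state_at(node_label)
        for element, result in reconstructions.items()
        if result.state_at(node_label) > 0
    }
    violations = []
    included: dict[str, int] = {}
    for element in sorted(raw):
        needed = registry.requires_closure(element)
        if needed <= set(raw):
            included[element] = raw[element]
        else:
            violations.append(
                f"{element}: requires {sorted(needed - set(raw))} absent at {node_label}")
    skeleton = _skeleton(included, registry)
    antler = AncestralAntler(node_label, included, skeleton, 0, violations)
    antler.point_count = count_points(antler, registry)
    return antler


def _skeleton(included: dict[str, int], registry: Registry) -> str:
    def expand(code: str) -> str:
        kids = sorted(e.code for e in registry.children_of(code) if e.code in included)
        if not kids:
            return code
        return f"{code}[{','.join(expand(k) for k in kids)}]"

    roots = sorted(c for c in included if registry.element(c).parent == "base")
    return ",".join(expand(r) for r in roots)


def count_points(antler: AncestralAntler, registry: Registry) -> int:
    """Number of free tips of tines and beams.

    A tine or beam contributes one point unless a present child arises at its
    terminal fork (which consumes its tip); processes never count.
    """
    present = antler.elements
    points = 0
    for code in present:
        el = registry.element(code)
        if el.category not in ("tine", "beam"):
            continue
        consumed = any(
            child.code in present and child.placement == "terminal"
            for child in registry.children_of(code)
        )
        if not consumed:
            points += 1
    return points
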