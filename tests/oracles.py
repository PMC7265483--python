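"""Independent brute-force oracles for the parsimony layer.

These enumerate complete ancestral assignments on small trees and never call
the implementation they check.
"""

from __future__ import annotations

from itertools import product

from antlerevo.trees import Tree


def rooted_shapes(n_leaves: int):
    """All rooted binary tree shapes with the given number of leaves,
    as nested tuples (leaves are None placeholders)."""
    if n_leaves == 1:
        return [None]
    shapes = []
    seen = set()
    for k in range(1, n_leaves):
        for left in rooted_shapes(k):
            for right in rooted_shapes(n_leaves - k):
                canon = _canon((left, right))
                if canon not in seen:
                    seen.add(canon)
                    shapes.append((left, right))
    return shapes


def _canon(shape):
    if shape is None:
        return "*"
    a, b = _canon(shape[0]), _canon(shape[1])
    return f"({min(a, b)},{max(a, b)})"


def shape_to_tree(shape) -> Tree:
    """Label leaves L0.. and internal nodes I0.. deterministically."""
    counter = {"leaf": 0, "int": 0}

    def build(s):
        if s is None:
            label = f"L{counter['leaf']}"
            counter["leaf"] += 1
            return label
        counter["int"] += 1
        label = f"I{counter['int']}"
        return f"({build(s[0])},{build(s[1])}){label}"

    return Tree.from_newick(build(shape) + ";")


def min_single_gain_losses(tree: Tree, tip_present: dict[str, bool]):
    """Minimum loss count over all single-gain presence histories.

    Enumerates every assignment of presence to internal nodes; a history is
    admissible when it has at most one gain (an absent->present edge, with a
    present root counting as a gain on its stem).  Returns ``(min_losses,
    n_minimal_assignments)`` or ``None`` when no admissible history exists.
    """
    internals = [n.label for n in tree.preorder() if not n.is_leaf]
    best, count = None, 0
    for bits in product([False, True], repeat=len(internals)):
        state = dict(zip(internals, bits))
        state.update(tip_present)
        gains = losses = 0
        for node in tree.preorder():
            parent = node.parent
            s = state[node.label]
            ps = state[parent.label] if parent is not None else False
            if not ps and s:
                gains += 1
            elif ps and not s:
                losses += 1
        if gains > 1 or (gains == 0 and any(tip_present.values())):
            continue
        if best is None or losses < best:
            best, count = losses, 1
        elif losses == best:
            count += 1
    return best, count


def minimal_grade_assignments(tree: Tree, tip_grades: dict[str, int]):
    """All minimal-change assignments of {1,2} to internal nodes.

    Returns ``(min_changes, assignments)`` where each assignment maps every
    node label to its grade.
    """
    internals = [n.label for n in tree.preorder() if not n.is_leaf]
    best, out = None, []
    for grades in product([1, 2], repeat=len(internals)):
        state = dict(zip(internals, grades))
        state.update(tip_grades)
        changes = sum(
            1
            for node in tree.preorder()
            if node.parent is not None
            and state[node.label] != state[node.parent.label]
        )
        if best is None or changes < best:
            best, out = changes, [state]
        elif changes == best:
            out.append(state)
    return best, out


def change_edges(tree: Tree, state: dict[str, int]) -> set[str]:
    return {
        node.label
        for node in tree.preorder()
        if node.parent is not None
        and state[node.label] != state[node.parent.label]
    }
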