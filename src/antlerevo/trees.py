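"""Rooted trees for topology-only parsimony.

Thin wrapper over dendropy's Newick parsing that exposes the structure the
reconstruction code needs: labelled nodes, parent pointers, deterministic
traversal orders, and MRCA queries.  Branch lengths are ignored throughout
(the methods here are parsimony on a fixed topology).

Edges are identified by the label of their child node ("stem edge of X" is
the edge connecting X to its parent; the root's stem edge is the root label).
"""

from __future__ import annotations

from typing import Iterable, Iterator

import dendropy

__all__ = ["TreeNode", "Tree"]


def _normalize(label: str) -> str:
    return label.replace("_", " ").strip()


class TreeNode:
    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str, parent: "TreeNode | None" = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent = parent

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r})"


class Tree:
    """A rooted (binary) tree with unique node labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._by_label: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.label in self._by_label:
                raise ValueError(f"duplicate node label: {node.label!r}")
            self._by_label[node.label] = node

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        """Parse a rooted Newick string.

        Leaf labels are normalized (underscores become spaces).  Unlabelled
        internal nodes receive deterministic ``nodeN`` labels in preorder.
        A basal polytomy is rejected: the methods implemented here are
        defined on a rooted binary topology.
        """
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        counter = [0]

        def convert(dnode, parent):
            if dnode.is_leaf():
                label = _normalize(dnode.taxon.label if dnode.taxon else dnode.label)
            else:
                label = dnode.label
                if not label:
                    counter[0] += 1
                    label = f"node{counter[0]}"
            node = TreeNode(label, parent)
            for child in dnode.child_nodes():
                node.children.append(convert(child, node))
            return node

        root = convert(dtree.seed_node, None)
        if len(root.children) != 2:
            raise ValueError(
                "tree root must be bifurcating (an unrooted/basal polytomy "
                f"with {len(root.children)} children was supplied)"
            )
        for node in _preorder(root):
            if node.children and len(node.children) != 2:
                raise ValueError(
                    f"node {node.label!r} is a polytomy; supply a binary tree"
                )
        return cls(root)

    @classmethod
    def from_newick_path(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- queries ---------------------------------------------------------

    def node(self, label: str) -> TreeNode:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def preorder(self) -> Iterator[TreeNode]:
        return _preorder(self.root)

    def postorder(self) -> Iterator[TreeNode]:
        return _postorder(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def depth(self, label: str) -> int:
        node, d = self.node(label), 0
        while node.parent is not None:
            node, d = node.parent, d + 1
        return d

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        labels = list(labels)
        if not labels:
            raise ValueError("mrca of an empty label set is undefined")
        paths = []
        for lab in labels:
            node, path = self.node(lab), []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def subtree_labels(self, label: str) -> set[str]:
        return {n.label for n in _preorder(self.node(label))}

    def clade_leaves(self, label: str) -> set[str]:
        return {n.label for n in _preorder(self.node(label)) if n.is_leaf}

    def is_monophyletic(self, leaf_labels: Iterable[str]) -> bool:
        leaf_labels = set(leaf_labels)
        return self.clade_leaves(self.mrca(leaf_labels).label) == leaf_labels


def _preorder(node: TreeNode) -> Iterator[TreeNode]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(reversed(n.children))


def _postorder(node: TreeNode) -> Iterator[TreeNode]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return iter(out[::-1])
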