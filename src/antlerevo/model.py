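"""Model / results interface to the ancestral-state reconstruction.

:class:`AntlerCharacterModel` bundles the data (a species x element
character-state matrix and the fixed rooted topology); :meth:`fit` runs the
hybrid Dollo + ACCTRAN reconstruction for every element and returns an
:class:`AntlerReconstructionResults` carrying per-element reconstructions,
per-node assembled ancestral antlers with point counts, diagnostics, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .coding import CharacterStateMatrix, SpecimenMatrix, code_matrix
from .parsimony import (AncestralAntler, ReconstructionResult,
                        assemble_ancestral_antler, reconstruct_character)
from .registry import Registry, load_registry
from .trees import Tree

__all__ = ["AntlerCharacterModel", "AntlerReconstructionResults"]


class AntlerCharacterModel:
    """Ancestral antler reconstruction on a fixed topology.

    Parameters
    ----------
    char_matrix
        Species x element states in {0, 1, 2} with coding provenance.
    tree
        Rooted binary topology whose leaves are the matrix species.
    registry
        Element catalogue supplying structural dependencies for antler
        assembly; defaults to the packaged registry.
    """

    def __init__(self, char_matrix: CharacterStateMatrix, tree: Tree,
                 registry: Registry | None = None):
        self.char_matrix = char_matrix
        self.tree = tree
        self.registry = registry or load_registry()
        leaves = set(tree.leaf_labels())
        species = set(char_matrix.species)
        if not leaves <= species:
            raise ValueError(
                f"tree leaves missing from the matrix: {sorted(leaves - species)}")

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_registry(cls, registry: Registry | None = None,
                      elements: list[str] | None = None) -> "AntlerCharacterModel":
        """Build from the packaged species-level frequency registry."""
        registry = registry or load_registry()
        matrix = CharacterStateMatrix.from_frequency_registry(registry, elements)
        return cls(matrix, registry.topology, registry)

    @classmethod
    def from_specimen_matrix(cls, specimens: SpecimenMatrix, tree: Tree,
                             registry: Registry | None = None
                             ) -> "AntlerCharacterModel":
        """Run the coding step on a specimen matrix, then build the model."""
        return cls(code_matrix(specimens), tree, registry)

    @classmethod
    def from_dataframe(cls, states: pd.DataFrame, tree: Tree,
                       registry: Registry | None = None) -> "AntlerCharacterModel":
        """Build from an already-coded species x element state frame."""
        pct = states.replace({0: 0.0, 1: 40.0, 2: 100.0}).astype(float)
        n = pd.Series(0, index=states.index, name="n_antlers")
        matrix = CharacterStateMatrix(states.astype(int), pct, n)
        return cls(matrix, tree, registry)

    # -- estimation ------------------------------------------------------

    def fit(self) -> "AntlerReconstructionResults":
        reconstructions: dict[str, ReconstructionResult] = {}
        for element in self.char_matrix.elements:
            tips = {leaf: int(self.char_matrix.states.loc[leaf, element])
                    for leaf in self.tree.leaf_labels()}
            reconstructions[element] = reconstruct_character(
                self.tree, tips, element=element)
        return AntlerReconstructionResults(self, reconstructions)


@dataclass
class AntlerReconstructionResults:
    """Fitted reconstruction: per-element histories and ancestral antlers."""

    model: AntlerCharacterModel
    reconstructions: dict[str, ReconstructionResult]
    _antlers: dict[str, AncestralAntler] = field(default_factory=dict, repr=False)

    @property
    def tree(self) -> Tree:
        return self.model.tree

    @property
    def elements(self) -> list[str]:
        return sorted(self.reconstructions)

    def reconstruction(self, element: str) -> ReconstructionResult:
        return self.reconstructions[element]

    def ancestral_antler(self, node_label: str) -> AncestralAntler:
        if node_label not in self._antlers:
            self._antlers[node_label] = assemble_ancestral_antler(
                node_label, self.reconstructions, self.model.registry)
        return self._antlers[node_label]

    # -- tables ----------------------------------------------------------

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for element in self.elements:
            for edge, event in self.reconstructions[element].events_table():
                rows.append({"element": element, "edge": edge, "event": event})
        return pd.DataFrame(rows, columns=["element", "edge", "event"])

    def node_states_frame(self) -> pd.DataFrame:
        labels = [n.label for n in self.tree.preorder()]
        return pd.DataFrame(
            {el: [self.reconstructions[el].state_at(l) for l in labels]
             for el in self.elements},
            index=labels)

    def character_summary(self) -> pd.DataFrame:
        rows = []
        for element in self.elements:
            r = self.reconstructions[element]
            rows.append({
                "element": element,
                "gain_edge": r.gain_edge or "-",
                "n_losses": len(r.loss_edges),
                "n_grade_changes": len(r.grade_change_edges),
            })
        return pd.DataFrame(rows).set_index("element")

    def node_summary(self, nodes: list[str] | None = None) -> pd.DataFrame:
        if nodes is None:
            nodes = [n.label for n in self.tree.preorder() if not n.is_leaf]
        rows = []
        for label in nodes:
            antler = self.ancestral_antler(label)
            rows.append({
                "node": label,
                "points": antler.point_count,
                "elements": " ".join(sorted(antler.elements)) or "-",
                "violations": len(antler.dependency_violations),
            })
        return pd.DataFrame(rows).set_index("node")

    def summary(self, nodes: list[str] | None = None) -> str:
        """Human-readable report of the fitted reconstruction."""
        n_sp = len(self.tree.leaf_labels())
        lines = [
            "Ancestral antler reconstruction (Dollo presence + ACCTRAN grades)",
            f"  species: {n_sp}    elements: {len(self.elements)}",
            "",
            "Per-element events",
            self.character_summary().to_string(),
            "",
            "Ancestral antlers",
            self.node_summary(nodes).to_string(),
        ]
        return "\n".join(lines)
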