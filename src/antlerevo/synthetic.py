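"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline: Dollo-consistent character histories on
the fixed tree (single gain, independent losses, 1<->2 grade drift),
Bernoulli specimen sampling from species-level frequencies (the inverse of
the coding step), and random tine trees with consistent fork geometry for
the projection and homology machinery.  All randomness flows from the
explicit seed in :class:`SimulationConfig`; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coding import METADATA_COLUMNS, SpecimenMatrix
from .projection import Fork, TineNode, TineTree
from .trees import Tree

__all__ = [
    "SimulationConfig",
    "simulate_dollo_character",
    "simulate_specimens",
    "synthetic_antler",
    "mirrored_pair",
]

#: Within-species sampling frequency of an element given its coded state.
DEFAULT_FREQUENCY_MAP = {2: 0.95, 1: 0.3, 0: 0.0}


@dataclass
class SimulationConfig:
    """Knobs of the three generators; every output records the seed."""

    seed: int = 0
    gain_edge: str | None = "random"
    loss_probability: float = 0.1
    grade_upgrade_probability: float = 0.9
    grade_downgrade_probability: float = 0.05
    specimens_per_species: int = 20
    frequency_map: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCY_MAP))

    def __post_init__(self):
        for name in ("loss_probability", "grade_upgrade_probability",
                     "grade_downgrade_probability"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.specimens_per_species <= 0:
            raise ValueError("specimens_per_species must be positive")
        for state, freq in self.frequency_map.items():
            if state not in (0, 1, 2) or not 0.0 <= freq <= 1.0:
                raise ValueError(f"bad frequency_map entry {state}: {freq}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "seed": self.seed, "gain_edge": self.gain_edge,
            "loss_probability": self.loss_probability,
            "grade_upgrade_probability": self.grade_upgrade_probability,
            "grade_downgrade_probability": self.grade_downgrade_probability,
            "specimens_per_species": self.specimens_per_species,
            "frequency_map": {int(k): float(v) for k, v in self.frequency_map.items()},
        })


def simulate_dollo_character(tree: Tree, config: SimulationConfig
                             ) -> tuple[dict[str, int], dict[str, int]]:
    """Evolve one element down the tree under the Dollo assumptions.

    The element arises (state 1, upgrading to 2 with the upgrade probability
    on the gain edge itself) only on ``config.gain_edge``; on each later edge
    a present lineage is lost for good with ``loss_probability``, otherwise
    its grade drifts 1->2 / 2->1.  Returns ``(node_states, tip_states)``.
    """
    rng = config.rng()
    labels = [n.label for n in tree.preorder()]
    gain = config.gain_edge
    if gain == "random":
        gain = labels[rng.integers(len(labels))]
    elif gain is not None and gain not in tree:
        raise ValueError(f"gain edge {gain!r} not in tree")

    states: dict[str, int] = {}
    for node in tree.preorder():
        parent_state = 0 if node.parent is None else states[node.parent.label]
        if node.label == gain:
            state = 1
            if rng.random() < config.grade_upgrade_probability:
                state = 2
        elif parent_state == 0:
            state = 0
        elif rng.random() < config.loss_probability:
            state = 0
        else:
            state = parent_state
            if state == 1 and rng.random() < config.grade_upgrade_probability:
                state = 2
            elif state == 2 and rng.random() < config.grade_downgrade_probability:
                state = 1
        states[node.label] = state
    tips = {n.label: states[n.label] for n in tree.leaves()}
    return states, tips


def simulate_specimens(species_states: dict[str, int], config: SimulationConfig,
                       element: str = "X") -> SpecimenMatrix:
    """Draw a specimen presence matrix from coded species states.

    Each adult antler of a species carries the element independently with
    ``frequency_map[state]``; left and right antlers are separate rows.
    Multiple elements can be drawn by passing a dict-of-dicts
    ``{element: {species: state}}``.
    """
    if species_states and isinstance(next(iter(species_states.values())), dict):
        per_element = species_states  # type: ignore[assignment]
    else:
        per_element = {element: species_states}
    rng = config.rng()
    species_list = sorted({s for mapping in per_element.values() for s in mapping})
    rows = []
    for species in species_list:
        for i in range(config.specimens_per_species):
            rows.append({
                "specimen_id": f"{species.replace(' ', '_')}_{i // 2:03d}",
                "species": species,
                "side": "left" if i % 2 == 0 else "right",
                "age_class": "adult",
            })
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS)
    for el in sorted(per_element):
        column = []
        for species in species_list:
            state = per_element[el].get(species, 0)
            freq = config.frequency_map.get(state, 0.0)
            column.extend(
                (rng.random(config.specimens_per_species) < freq).astype(int))
        df[el] = column
    return SpecimenMatrix(df)


# ---------------------------------------------------------------------------
# random tine trees
# ---------------------------------------------------------------------------

def synthetic_antler(config: SimulationConfig, depth: int = 2,
                     side: str = "left") -> TineTree:
    """Random antler with consistent fork geometry.

    ``depth`` is the number of nested forks down the main stem (0 gives a
    single spike).  All lengths and diameters are positive, fork windows are
    non-degenerate, and the result satisfies every tine-tree invariant, so
    diagram assembly always succeeds on the output.
    """
    rng = config.rng()
    counter = [0]

    def new_code() -> str:
        counter[0] += 1
        return f"E{counter[0]}"

    def segment(code: str, levels: int, is_root: bool) -> TineNode:
        length = float(rng.uniform(8.0, 40.0))
        diameter = float(rng.uniform(1.0, max(1.5, length / 4.0)))
        circumference = float(np.pi * diameter)
        node = TineNode(code=code, category="tine", length=length,
                        diameter=diameter, circumference=circumference)
        if levels > 0:
            ridge = 0.0 if is_root else float(rng.uniform(0.05, 0.35))
            boundary = float(rng.uniform(ridge + 0.2, min(ridge + 0.55, 0.95)))
            node.fork = Fork(ridge, boundary)
            branch_levels = int(rng.integers(0, levels)) if levels > 1 else 0
            node.children = [
                segment(new_code(), branch_levels, False),
                segment(new_code(), levels - 1, False),
            ]
            node.category = "beam"
        return node

    if depth == 0:
        root = segment(new_code(), 0, True)
        return TineTree(root, side=side)
    root = segment("base", depth, True)
    skull = {"SR": float(rng.uniform(0.0, 30.0)),
             "TR": float(rng.uniform(100.0, 150.0)),
             "BN": float(rng.uniform(180.0, 220.0))}
    return TineTree(root, side=side, skull_marks=skull)


def mirrored_pair(config: SimulationConfig, depth: int = 2
                  ) -> tuple[TineTree, TineTree]:
    """A left antler and its mirror-image right twin (same local geometry)."""
    left = synthetic_antler(config, depth=depth, side="left")
    right = TineTree(left.root, side="right", skull_marks=left.skull_marks)
    return left, right
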