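"""Packaged domain model: element catalogue, skull indices, species table,
species-level element frequencies, and the fixed species topology.

The registry replicates the study system this package models: 25 cervid
species in 16 genera, the named antler elements (tines, beams, processes)
with their structural attachment, the seven skull indices marked on the burr
cross-section, and a fixed rooted molecular topology with labelled clades.
Species-level element frequencies are recorded either as percentages or as
qualitative classes; :func:`resolve_frequency` maps both onto [0, 100].
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .trees import Tree

__all__ = [
    "AntlerElement",
    "SkullIndex",
    "SpeciesRecord",
    "FrequencyRegistry",
    "Registry",
    "load_registry",
    "resolve_frequency",
    "QUALITATIVE_FREQUENCIES",
    "SKULL_INDEX_CODES",
]

#: Fixed mapping of qualitative frequency classes to percentages.  Chosen so
#: that coding a qualitative class reproduces the character state the class
#: implies: all/almost_all -> state 2 (>= 80%), common/rare/very_rare ->
#: state 1 (observed, < 80%), absent -> state 0.
QUALITATIVE_FREQUENCIES: dict[str, float] = {
    "all": 100.0,
    "almost_all": 95.0,
    "common": 50.0,
    "rare": 10.0,
    "very_rare": 2.0,
    "absent": 0.0,
}

SKULL_INDEX_CODES = frozenset({"SR", "TR", "IFST", "SPO", "LMOF", "PEOI", "BN"})

_CATEGORIES = frozenset({"tine", "beam", "process"})


def resolve_frequency(entry) -> float:
    """Resolve a frequency-class entry to a percentage in [0, 100].

    Numeric entries pass through unchanged; qualitative tokens use the fixed
    :data:`QUALITATIVE_FREQUENCIES` table.
    """
    if isinstance(entry, (int, float)) and not isinstance(entry, bool):
        pct = float(entry)
        if not 0.0 <= pct <= 100.0:
            raise ValueError(f"frequency percentage {pct} outside [0, 100]")
        return pct
    if isinstance(entry, str):
        try:
            return QUALITATIVE_FREQUENCIES[entry]
        except KeyError:
            raise ValueError(f"unknown frequency class {entry!r}") from None
    raise ValueError(f"invalid frequency entry: {entry!r}")


@dataclass(frozen=True)
class AntlerElement:
    """One homologous antler element.

    ``parent`` is the element this one branches from (``"base"`` for the two
    elements arising at the burr); ``placement`` is ``"terminal"`` when the
    element arises at the terminal fork of its parent (consuming the parent's
    tip when counting points) and ``"lateral"`` for a side branch.
    ``requires`` is the set of element codes that must be present for this
    element to attach.
    """

    code: str
    name: str
    category: str
    parent: str
    placement: str
    pocock_code: str | None = None

    @property
    def requires(self) -> frozenset[str]:
        return frozenset() if self.parent == "base" else frozenset({self.parent})


@dataclass(frozen=True)
class SkullIndex:
    code: str
    description: str
    default_angle_deg: float


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    genus: str
    n_antlers: int
    clade_tags: frozenset[str]


@dataclass
class FrequencyRegistry:
    """(species, element) -> frequency class; unlisted pairs are absent."""

    entries: dict[str, dict[str, object]]

    def get(self, species: str, element: str):
        return self.entries.get(species, {}).get(element, "absent")

    def percentage(self, species: str, element: str) -> float:
        return resolve_frequency(self.get(species, element))

    def elements_recorded(self) -> list[str]:
        codes: set[str] = set()
        for mapping in self.entries.values():
            codes.update(mapping)
        return sorted(codes)


@dataclass
class Registry:
    elements: dict[str, AntlerElement]
    skull_indices: dict[str, SkullIndex]
    species: dict[str, SpeciesRecord]
    frequencies: FrequencyRegistry
    topology: Tree
    named_clades: dict[str, set[str]] = field(default_factory=dict)

    # -- element structure ----------------------------------------------

    def element(self, code: str) -> AntlerElement:
        try:
            return self.elements[code]
        except KeyError:
            raise KeyError(f"unknown element code {code!r}") from None

    def requires_closure(self, code: str) -> frozenset[str]:
        """Transitive structural prerequisites of an element."""
        out: set[str] = set()
        stack = [code]
        while stack:
            parent = self.element(stack.pop()).parent
            if parent != "base" and parent not in out:
                out.add(parent)
                stack.append(parent)
        return frozenset(out)

    def children_of(self, code: str) -> list[AntlerElement]:
        return [e for e in self.elements.values() if e.parent == code]

    # -- species / tree -------------------------------------------------

    def genera(self) -> set[str]:
        return {rec.genus for rec in self.species.values()}

    def validate(self) -> None:
        """Check every packaged-fixture invariant; raise ValueError on failure."""
        for el in self.elements.values():
            if el.category not in _CATEGORIES:
                raise ValueError(f"element {el.code}: bad category {el.category!r}")
            if el.parent != "base" and el.parent not in self.elements:
                raise ValueError(f"element {el.code}: unknown parent {el.parent!r}")
            if el.placement not in ("terminal", "lateral"):
                raise ValueError(f"element {el.code}: bad placement {el.placement!r}")
        for code in self.elements:
            seen: set[str] = set()
            cur = code
            while cur != "base":
                if cur in seen:
                    raise ValueError(f"element dependency cycle through {code!r}")
                seen.add(cur)
                cur = self.elements[cur].parent
        if set(self.skull_indices) != SKULL_INDEX_CODES:
            raise ValueError("skull index codes must be exactly the seven known ones")
        for rec in self.species.values():
            if rec.n_antlers < 0:
                raise ValueError(f"{rec.species}: negative antler count")
        leaves = set(self.topology.leaf_labels())
        if leaves != set(self.species):
            missing = leaves ^ set(self.species)
            raise ValueError(f"topology leaves and species table differ: {sorted(missing)}")
        for species in self.frequencies.entries:
            if species not in self.species:
                raise ValueError(f"frequency registry lists unknown species {species!r}")
            for element, entry in self.frequencies.entries[species].items():
                if element not in self.elements:
                    raise ValueError(f"frequency registry lists unknown element {element!r}")
                resolve_frequency(entry)
        for name, members in self.named_clades.items():
            if not self.topology.is_monophyletic(members):
                raise ValueError(f"named clade {name!r} is not monophyletic in the tree")


_DEFAULT_CLADE_TAGS = ("Cervinae", "Cervini", "Muntiacini", "Capreolinae",
                       "Capreolini", "Alceini", "Odocoileini")


def _data_path(name: str, config_dir: str | Path | None) -> Path:
    if config_dir is not None:
        path = Path(config_dir) / name
    else:
        path = Path(str(resources.files("antlerevo").joinpath("data", name)))
    if not path.exists():
        raise FileNotFoundError(f"missing registry fixture file: {path}")
    return path


def load_registry(config_dir: str | Path | None = None) -> Registry:
    """Load and validate the packaged registry (or a replacement directory).

    The directory must contain ``elements.json``, ``skull_indices.json``,
    ``species.csv``, ``frequencies.json`` and ``topology.nwk``.
    """
    with open(_data_path("elements.json", config_dir)) as fh:
        raw = json.load(fh)["elements"]
    elements: dict[str, AntlerElement] = {}
    for item in raw:
        el = AntlerElement(
            code=item["code"], name=item["name"], category=item["category"],
            parent=item["parent"], placement=item["placement"],
            pocock_code=item.get("pocock_code"),
        )
        if el.code in elements:
            raise ValueError(f"duplicate element code {el.code!r}")
        elements[el.code] = el

    with open(_data_path("skull_indices.json", config_dir)) as fh:
        raw = json.load(fh)["indices"]
    skull = {
        code: SkullIndex(code, item["description"], float(item["default_angle_deg"]))
        for code, item in raw.items()
    }

    species: dict[str, SpeciesRecord] = {}
    with open(_data_path("species.csv", config_dir), newline="") as fh:
        for row in csv.DictReader(fh):
            rec = SpeciesRecord(
                species=row["species"], genus=row["genus"],
                n_antlers=int(row["n_antlers"]),
                clade_tags=frozenset(row["clade_tags"].split(";")),
            )
            if rec.species in species:
                raise ValueError(f"duplicate species {rec.species!r}")
            species[rec.species] = rec

    with open(_data_path("frequencies.json", config_dir)) as fh:
        freqs = FrequencyRegistry(json.load(fh)["frequencies"])

    topology = Tree.from_newick_path(_data_path("topology.nwk", config_dir))

    named_clades = {
        name: {rec.species for rec in species.values() if name in rec.clade_tags}
        for name in _DEFAULT_CLADE_TAGS
    }
    named_clades["Cervidae"] = set(species)

    reg = Registry(elements, skull, species, freqs, topology, named_clades)
    reg.validate()
    return reg
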