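"""Character coding: specimen presence matrices -> species percentages ->
the three-state presence characters used for ancestral reconstruction.

State 2: the element occurs in at least 80% of a species' adult antlers.
State 1: observed, but in fewer than 80%.
State 0: never observed.  Any single observation therefore forces state >= 1.

Left and right antlers are counted separately; juvenile and unknown-age rows
are excluded from coding (they remain usable for diagram work).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registry import Registry

__all__ = [
    "METADATA_COLUMNS",
    "SpecimenMatrix",
    "CharacterStateMatrix",
    "species_percentages",
    "code_state",
    "code_matrix",
]

METADATA_COLUMNS = ["specimen_id", "species", "side", "age_class"]


@dataclass
class SpecimenMatrix:
    """Per-antler element presence with specimen metadata.

    Wraps a DataFrame whose first columns are :data:`METADATA_COLUMNS` and
    whose remaining columns are element codes with values in {0, 1}.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"specimen matrix lacks metadata columns {missing}")
        elements = self.element_columns
        if not elements:
            raise ValueError("specimen matrix has no element columns")
        block = df[elements]
        if block.isna().any().any():
            raise ValueError("missing presence cells are not allowed")
        if not block.isin([0, 1]).all().all():
            raise ValueError("element presence values must be 0 or 1")
        dup = df.duplicated(subset=["specimen_id", "side"])
        if dup.any():
            raise ValueError(
                f"duplicate (specimen id, side) rows: "
                f"{df.loc[dup, ['specimen_id', 'side']].values.tolist()}")
        bad_side = ~df["side"].isin(["left", "right"])
        if bad_side.any():
            raise ValueError(f"side must be left/right: {sorted(df.loc[bad_side, 'side'])}")

    @property
    def element_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in METADATA_COLUMNS]

    @property
    def adults(self) -> pd.DataFrame:
        return self.data[self.data["age_class"] == "adult"]

    @classmethod
    def from_csv(cls, path) -> "SpecimenMatrix":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def validate_species(self, registry: Registry) -> None:
        unknown = set(self.data["species"]) - set(registry.species)
        if unknown:
            raise ValueError(f"species not in the species table: {sorted(unknown)}")


def species_percentages(matrix: SpecimenMatrix
                        ) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Per-species element percentages over adult antlers.

    Returns ``(percentages, n_adult_antlers, excluded_species)``: species
    with zero adult antlers have undefined percentages and are reported in
    ``excluded_species`` rather than guessed.  Percentages are carried at
    full precision.
    """
    adults = matrix.adults
    all_species = sorted(set(matrix.data["species"]))
    counts = adults.groupby("species").size()
    excluded = [s for s in all_species if counts.get(s, 0) == 0]
    grouped = adults.groupby("species")[matrix.element_columns].mean() * 100.0
    n = counts.reindex(grouped.index).astype(int)
    n.name = "n_antlers"
    return grouped, n, excluded


def code_state(pct: float) -> int:
    """Code one percentage into the three-state character."""
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentage {pct} outside [0, 100]")
    if pct >= 80.0:
        return 2
    if pct > 0.0:
        return 1
    return 0


@dataclass
class CharacterStateMatrix:
    """Species x element states in {0,1,2} with coding provenance."""

    states: pd.DataFrame
    percentages: pd.DataFrame
    n_antlers: pd.Series

    def __post_init__(self):
        if not self.states.isin([0, 1, 2]).all().all():
            raise ValueError("character states must be 0, 1 or 2")
        for species in self.states.index:
            for element in self.states.columns:
                pct = self.percentages.loc[species, element]
                expected = code_state(pct)
                if self.states.loc[species, element] != expected:
                    raise ValueError(
                        f"state/percentage mismatch for ({species}, {element}): "
                        f"{self.states.loc[species, element]} vs pct {pct}")

    @property
    def elements(self) -> list[str]:
        return list(self.states.columns)

    @property
    def species(self) -> list[str]:
        return list(self.states.index)

    def tip_states(self, element: str) -> dict[str, int]:
        return self.states[element].to_dict()

    @classmethod
    def from_frequency_registry(cls, registry: Registry,
                                elements: list[str] | None = None
                                ) -> "CharacterStateMatrix":
        """Code states directly from the species-level frequency registry."""
        elements = elements or registry.frequencies.elements_recorded()
        species = sorted(registry.species)
        pct = pd.DataFrame(
            [[registry.frequencies.percentage(s, e) for e in elements]
             for s in species],
            index=species, columns=elements, dtype=float)
        states = pct.map(code_state)
        n = pd.Series({s: registry.species[s].n_antlers for s in species},
                      name="n_antlers")
        return cls(states.astype(int), pct, n)

    @classmethod
    def from_specimens(cls, matrix: SpecimenMatrix) -> "CharacterStateMatrix":
        pct, n, excluded = species_percentages(matrix)
        if excluded:
            raise ValueError(
                f"species without adult antlers cannot be coded: {excluded}")
        states = pct.apply(lambda col: col.map(code_state)).astype(int)
        return cls(states, pct, n)

    def to_csv(self, path) -> None:
        self.states.to_csv(path, index_label="species")

    def to_nexus(self) -> str:
        """Simple NEXUS-style character block for interoperability."""
        taxa = [s.replace(" ", "_") for s in self.species]
        width = max(len(t) for t in taxa) + 2
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(taxa)} NCHAR={len(self.elements)};",
            '  FORMAT DATATYPE=STANDARD SYMBOLS="012" MISSING=?;',
            "  MATRIX",
        ]
        for species, taxon in zip(self.species, taxa):
            row = "".join(str(int(v)) for v in self.states.loc[species])
            lines.append(f"    {taxon:<{width}}{row}")
        lines += ["  ;", "END;", ""]
        return "\n".join(lines)


def code_matrix(matrix: SpecimenMatrix) -> CharacterStateMatrix:
    """Full coding step: adult filter, percentages, state assignment."""
    return CharacterStateMatrix.from_specimens(matrix)
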