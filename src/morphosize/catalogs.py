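"""Variable catalogs for traditional-morphometric measurement sets.

A catalog declares, per anatomical structure, the ordered list of measured
variables: linear distances (mm, strictly positive) and angles (degrees,
never size-standardized).  Catalogs for the horse cranium (9 linear
variables), bony labyrinth (7 linear) and braincase endocast (9 linear +
4 angle) ship as packaged CSV files; user catalogs in the same format can
be loaded with :func:`read_catalog`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

VariableKind = Literal["linear", "angle"]

STRUCTURES = ("cranium", "bony_labyrinth", "brain_endocast")


@dataclass(frozen=True)
class VariableDef:
    """One measured variable: its name, short token, kind and units."""

    name: str
    abbreviation: str
    kind: VariableKind
    units: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "angle"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        units = self.units or ("mm" if self.kind == "linear" else "degrees")
        object.__setattr__(self, "units", units)
        expected = "mm" if self.kind == "linear" else "degrees"
        if self.units != expected:
            raise ValueError(
                f"variable {self.abbreviation!r}: kind={self.kind} requires "
                f"units={expected!r}, got {self.units!r}"
            )


@dataclass(frozen=True)
class VariableCatalog:
    """Ordered collection of :class:`VariableDef` for one structure."""

    structure: str
    variables: tuple[VariableDef, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        abbrevs = [v.abbreviation for v in self.variables]
        if len(set(abbrevs)) != len(abbrevs):
            dupes = sorted({a for a in abbrevs if abbrevs.count(a) > 1})
            raise ValueError(f"duplicate abbreviations in catalog: {dupes}")

    @property
    def abbreviations(self) -> list[str]:
        return [v.abbreviation for v in self.variables]

    @property
    def linear_abbreviations(self) -> list[str]:
        return [v.abbreviation for v in self.variables if v.kind == "linear"]

    @property
    def angle_abbreviations(self) -> list[str]:
        return [v.abbreviation for v in self.variables if v.kind == "angle"]

    @property
    def angle_mask(self) -> list[bool]:
        """Boolean per variable, True where the variable is an angle."""
        return [v.kind == "angle" for v in self.variables]

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterable[VariableDef]:
        return iter(self.variables)

    def __getitem__(self, abbreviation: str) -> VariableDef:
        for v in self.variables:
            if v.abbreviation == abbreviation:
                return v
        raise KeyError(abbreviation)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariableCatalog):
            return NotImplemented
        return (
            self.structure == other.structure and self.variables == other.variables
        )

    def __hash__(self) -> int:
        return hash((self.structure, self.variables))


def _catalog_from_frame(structure: str, df: pd.DataFrame) -> VariableCatalog:
    required = {"abbreviation", "name", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog file missing columns: {sorted(missing)}")
    variables = [
        VariableDef(
            name=row["name"],
            abbreviation=row["abbreviation"],
            kind=row["kind"],
            units=row.get("units", "") or "",
            description=row.get("description", "") or "",
        )
        for _, row in df.iterrows()
    ]
    return VariableCatalog(structure=structure, variables=tuple(variables))


def read_catalog(path: str | Path, structure: str | None = None) -> VariableCatalog:
    """Load a catalog from a CSV with columns abbreviation,name,kind[,units,description]."""
    path = Path(path)
    df = pd.read_csv(path).fillna("")
    return _catalog_from_frame(structure or path.stem, df)


def load_catalog(structure: str) -> VariableCatalog:
    """Load one of the packaged catalogs: cranium, bony_labyrinth or brain_endocast."""
    if structure not in STRUCTURES:
        raise KeyError(
            f"unknown structure {structure!r}; packaged catalogs: {STRUCTURES}"
        )
    ref = resources.files("morphosize.data").joinpath(f"{structure}.csv")
    with resources.as_file(ref) as path:
        return read_catalog(path, structure=structure)
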