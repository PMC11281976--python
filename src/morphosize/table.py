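"""Measurement tables: specimens x variables matrices with specimen metadata.

The universal currency of the pipeline is the :class:`MeasurementTable`: a
numeric matrix (one row per specimen, one column per catalog variable, NaN
for missing cells) paired with per-specimen metadata (breed, group,
maturity, ...).  Reading, validation, the sampling filters (mature-only,
complete-cases-only) and table merging live here.

Sampling rules encoded:

* only skeletally mature specimens enter the analyses (``filter_mature``;
  unknown maturity is dropped by default, conservatively);
* specimens with any missing measurement are excluded listwise
  (``filter_complete``) — no imputation;
* non-positive linear measurements and out-of-range angles are coerced to
  missing with a warning, so one bad cell costs one specimen rather than
  the whole run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import VariableCatalog

#: Metadata columns recognised in delimited files, in canonical order.
META_COLUMNS = (
    "specimen_id",
    "breed",
    "group",
    "maturity",
    "sex",
    "age",
    "locality",
    "source",
)

MATURITY_LEVELS = ("mature", "immature", "unknown")


@dataclass(frozen=True)
class FilterReport:
    """Outcome of a sampling filter: which specimens were dropped and why."""

    rule: str
    n_before: int
    n_after: int
    dropped_ids: tuple[str, ...]

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_ids)


@dataclass
class MeasurementTable:
    """Specimens x variables measurement matrix plus per-specimen metadata.

    Parameters
    ----------
    catalog
        Variable catalog; ``values`` columns must match its abbreviations
        in order.
    values
        Numeric DataFrame indexed by specimen_id.  NaN marks missing.
    meta
        Metadata DataFrame on the same index with columns
        ``breed, group, maturity, sex, age, locality, source``.
    """

    catalog: VariableCatalog
    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = self.catalog.abbreviations
        got = list(self.values.columns)
        if got != expected:
            if set(got) >= set(expected):
                self.values = self.values[expected]
            else:
                missing = sorted(set(expected) - set(got))
                raise ValueError(f"values missing catalog columns: {missing}")
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise ValueError(f"duplicate specimen_id: {dupes}")
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.index.name = "specimen_id"
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.values.index)
        self.meta = self.meta.reindex(self.values.index)
        for col in META_COLUMNS[1:]:
            if col not in self.meta.columns:
                self.meta[col] = "unknown" if col == "maturity" else ""
        self.meta = self.meta[list(META_COLUMNS[1:])].fillna("").astype(str)
        self.meta.loc[~self.meta["maturity"].isin(MATURITY_LEVELS), "maturity"] = (
            "unknown"
        )
        self._coerce_invalid_cells()

    def _coerce_invalid_cells(self) -> None:
        # lengths must be positive; angles must lie in (0, 360)
        for abbrev in self.catalog.linear_abbreviations:
            bad = self.values[abbrev].notna() & (self.values[abbrev] <= 0)
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} non-positive value(s) in linear variable "
                    f"{abbrev!r} coerced to missing "
                    f"(specimens: {list(self.values.index[bad])})",
                    stacklevel=3,
                )
                self.values.loc[bad, abbrev] = np.nan
        for abbrev in self.catalog.angle_abbreviations:
            col = self.values[abbrev]
            bad = col.notna() & ((col <= 0) | (col >= 360))
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} out-of-range angle(s) in {abbrev!r} "
                    f"coerced to missing",
                    stacklevel=3,
                )
                self.values.loc[bad, abbrev] = np.nan

    # -- basic properties -------------------------------------------------
    @property
    def specimen_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_specimens(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0

    def subset(self, ids: Sequence[str]) -> "MeasurementTable":
        """Row subset preserving the original row order."""
        keep = [i for i in self.specimen_ids if i in set(ids)]
        return MeasurementTable(
            catalog=self.catalog,
            values=self.values.loc[keep].copy(),
            meta=self.meta.loc[keep].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame with metadata columns followed by measurements."""
        out = self.meta.copy()
        out.insert(0, "specimen_id", self.values.index)
        return pd.concat(
            [out.reset_index(drop=True),
             self.values.reset_index(drop=True)], axis=1
        )


def read_table(
    path: str | Path,
    catalog: VariableCatalog,
    column_map: Mapping[str, str] | None = None,
) -> MeasurementTable:
    """Read a measurement table from CSV/TSV or a spreadsheet.

    Parameters
    ----------
    path
        Delimited text (``.csv``, ``.tsv``, ``.txt``) or spreadsheet
        (``.xlsx``, read-only).
    catalog
        Catalog whose abbreviations the file's columns must cover.
    column_map
        Optional mapping from catalog abbreviation (or canonical metadata
        name) to the column name actually used in the file.

    Raises
    ------
    ValueError
        If a required measurement column is absent (the error names it) or
        a specimen_id occurs twice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        # round_trip: re-reading a written table must be bit-exact
        raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    column_map = dict(column_map or {})
    rename = {v: k for k, v in column_map.items() if v in raw.columns}
    raw = raw.rename(columns=rename)

    missing = [a for a in catalog.abbreviations if a not in raw.columns]
    if missing:
        raise ValueError(
            f"input {path.name} lacks required measurement column(s): "
            f"{', '.join(missing)}"
        )
    if "specimen_id" not in raw.columns:
        raise ValueError(f"input {path.name} lacks required column: specimen_id")
    ids = raw["specimen_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate specimen_id in {path.name}: {dupes}")

    values = raw[catalog.abbreviations].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(ids, name="specimen_id")
    meta_cols = [c for c in META_COLUMNS[1:] if c in raw.columns]
    meta = raw[meta_cols].copy() if meta_cols else pd.DataFrame(index=values.index)
    meta.index = values.index
    return MeasurementTable(catalog=catalog, values=values, meta=meta)


def write_table(table: MeasurementTable, path: str | Path) -> None:
    """Write a table as UTF-8 CSV (header = metadata names + abbreviations)."""
    table.to_frame().to_csv(path, index=False)


def filter_mature(
    table: MeasurementTable, drop_unknown: bool = True
) -> tuple[MeasurementTable, FilterReport]:
    """Keep skeletally mature specimens.

    ``maturity == 'unknown'`` is dropped by default (the analyses admit only
    confirmed-mature individuals); pass ``drop_unknown=False`` to retain.
    """
    allowed = {"mature"} if drop_unknown else {"mature", "unknown"}
    keep = table.meta["maturity"].isin(allowed)
    dropped = tuple(table.values.index[~keep])
    out = table.subset(list(table.values.index[keep]))
    return out, FilterReport("mature_only", table.n_specimens, out.n_specimens, dropped)


def filter_complete(
    table: MeasurementTable,
) -> tuple[MeasurementTable, FilterReport]:
    """Keep specimens with no missing value in any catalog variable.

    Raises
    ------
    ValueError
        If no specimen is complete (downstream PCA would be undefined).
    """
    keep = table.values.notna().all(axis=1)
    dropped = tuple(table.values.index[~keep])
    if not keep.any():
        raise ValueError(
            "no specimen has complete measurements; nothing left to analyse"
        )
    out = table.subset(list(table.values.index[keep]))
    return out, FilterReport(
        "complete_cases", table.n_specimens, out.n_specimens, dropped
    )


def merge_tables(a: MeasurementTable, b: MeasurementTable) -> MeasurementTable:
    """Concatenate two tables sharing a catalog; specimen ids must not collide."""
    if a.catalog != b.catalog:
        raise ValueError(
            f"catalog mismatch: {a.catalog.structure!r} with "
            f"{len(a.catalog)} variables vs {b.catalog.structure!r} with "
            f"{len(b.catalog)}"
        )
    collisions = set(a.specimen_ids) & set(b.specimen_ids)
    if collisions:
        raise ValueError(f"specimen_id collision on merge: {sorted(collisions)}")
    return MeasurementTable(
        catalog=a.catalog,
        values=pd.concat([a.values, b.values]),
        meta=pd.concat([a.meta, b.meta]),
    )


def assign_groups(
    table: MeasurementTable,
    group_map: Mapping[str, str],
    default: str = "Comparative",
) -> MeasurementTable:
    """Return a copy with ``group`` metadata set from a breed -> group mapping."""
    meta = table.meta.copy()
    meta["group"] = [group_map.get(b, default) for b in meta["breed"]]
    return replace(table, values=table.values.copy(), meta=meta)
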