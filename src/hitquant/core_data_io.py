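"""Validated record types and CSV readers/writers for vial-level mortality data.

The package's canonical tidy schemas:

``vials``        study_id, block, group_id, unit_id, treatment, n_flies, n_dead
``mi_records``   group_id, unit_id, mi, n_hit, n_sham, baseline_mode [, block]
``masses``       group_id, sex, dry_mass
``line_traits``  line_id, <one column per trait>

A vial is the unit of observation: a group of flies either subjected to
high-impact trauma (``hit``) or handled identically without impact (``sham``),
scored for deaths at 24 h.  Counts are stored as integers and proportions are
always derived, never stored.  An optional ``schema_map`` (canonical name ->
column name in the file) absorbs foreign layouts such as published
supplementary tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TREATMENT_LABELS = ("hit", "sham")
BASELINE_MODES = ("paired", "pooled")
SEX_LABELS = ("male", "female")

VIAL_COLUMNS = ("study_id", "block", "group_id", "unit_id",
                "treatment", "n_flies", "n_dead")
MI_COLUMNS = ("group_id", "unit_id", "mi", "n_hit", "n_sham", "baseline_mode")
MASS_COLUMNS = ("group_id", "sex", "dry_mass")


class SchemaError(ValueError):
    """A required column is missing or the file layout is unusable."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message names row and field."""


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VialCount:
    """One vial's flies-at-risk and 24-h deaths, with its grouping keys."""

    study_id: str
    block: str
    group_id: str
    unit_id: str
    treatment: str
    n_flies: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENT_LABELS:
            raise ValidationError(
                f"treatment must be one of {TREATMENT_LABELS}, got {self.treatment!r}")
        if self.n_flies < 0 or self.n_dead < 0:
            raise ValidationError(
                f"counts must be non-negative (n_flies={self.n_flies}, n_dead={self.n_dead})")
        if self.n_dead > self.n_flies:
            raise ValidationError(
                f"n_dead ({self.n_dead}) exceeds n_flies ({self.n_flies})")

    @property
    def proportion_dead(self) -> float:
        if self.n_flies == 0:
            raise ValidationError("proportion undefined for an empty vial (n_flies=0)")
        return self.n_dead / self.n_flies


@dataclass(frozen=True)
class MIRecord:
    """A mortality-index value (percent) for one experimental unit.

    ``mi`` is 100 x (hit proportion dead - sham baseline proportion).  In the
    paired design the baseline is the unit's own sham vial (``n_sham`` > 0);
    in the pooled design the baseline is an average over all sham vials of the
    group and ``n_sham`` is 0.
    """

    group_id: str
    unit_id: str
    mi: float
    n_hit: int
    n_sham: int
    baseline_mode: str
    block: str = ""

    def __post_init__(self) -> None:
        if self.baseline_mode not in BASELINE_MODES:
            raise ValidationError(
                f"baseline_mode must be one of {BASELINE_MODES}, got {self.baseline_mode!r}")
        if not -100.0 <= self.mi <= 100.0:
            raise ValidationError(f"mi must lie in [-100, 100], got {self.mi}")
        if self.baseline_mode == "paired" and self.n_sham <= 0:
            raise ValidationError("paired baseline requires n_sham > 0")


@dataclass(frozen=True)
class MassRecord:
    """One fly's dry body mass in milligrams."""

    group_id: str
    sex: str
    dry_mass: float

    def __post_init__(self) -> None:
        if self.sex not in SEX_LABELS:
            raise ValidationError(f"sex must be one of {SEX_LABELS}, got {self.sex!r}")
        if not math.isfinite(self.dry_mass) or self.dry_mass < 0:
            raise ValidationError(f"dry_mass must be finite and >= 0, got {self.dry_mass}")


class LineTraitTable:
    """Line-level trait means (e.g. DGRP-style), one row per line.

    Missing values are permitted per trait; each pairwise analysis uses only
    rows complete for both traits.
    """

    def __init__(self, df: pd.DataFrame):
        if "line_id" not in df.columns:
            raise SchemaError("line trait table requires a 'line_id' column")
        ids = df["line_id"].astype(str)
        dup = ids[ids.duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate line_id values: {sorted(set(dup))}")
        self._df = df.copy()
        self._df["line_id"] = ids

    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    @property
    def line_ids(self) -> list[str]:
        return list(self._df["line_id"])

    @property
    def traits(self) -> list[str]:
        return [c for c in self._df.columns if c != "line_id"]

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineTraitTable):
            return NotImplemented
        return self._df.equals(other._df)

    def trait_values(self, trait: str) -> np.ndarray:
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}; available: {self.traits}")
        return self._df[trait].to_numpy(dtype=float)

    def complete_pairs(self, trait_x: str, trait_y: str) -> tuple[np.ndarray, np.ndarray]:
        """Values for two traits restricted to lines complete for both."""
        x = self.trait_values(trait_x)
        y = self.trait_values(trait_y)
        ok = np.isfinite(x) & np.isfinite(y)
        return x[ok], y[ok]


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def _apply_schema_map(df: pd.DataFrame, required: Sequence[str],
                      schema_map: Mapping[str, str] | None) -> pd.DataFrame:
    if schema_map:
        rename = {v: k for k, v in schema_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _int_cell(value, row: int, col: str) -> int:
    if value is None or (isinstance(value, float) and math.isnan(value)) or \
            (isinstance(value, str) and not value.strip()):
        raise ValidationError(f"row {row}: blank/NA value in column '{col}'")
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: non-numeric value {value!r} in column '{col}'")
    if not f.is_integer():
        raise ValidationError(f"row {row}: non-integer count {value!r} in column '{col}'")
    return int(f)


def read_vials(path: str | Path,
               schema_map: Mapping[str, str] | None = None) -> list[VialCount]:
    """Read a vials CSV, validating every row against the VialCount invariants.

    Row order is preserved.  Validation errors cite the offending (0-based
    data) row and field; there is no silent coercion.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _apply_schema_map(df, VIAL_COLUMNS, schema_map)
    out: list[VialCount] = []
    for i, row in enumerate(df.itertuples(index=False)):
        treatment = str(getattr(row, "treatment")).strip().lower()
        try:
            rec = VialCount(
                study_id=str(getattr(row, "study_id")),
                block=str(getattr(row, "block")),
                group_id=str(getattr(row, "group_id")),
                unit_id=str(getattr(row, "unit_id")),
                treatment=treatment,
                n_flies=_int_cell(getattr(row, "n_flies"), i, "n_flies"),
                n_dead=_int_cell(getattr(row, "n_dead"), i, "n_dead"),
            )
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
        out.append(rec)
    return out


def write_vials(records: Iterable[VialCount], path: str | Path) -> None:
    """Write vials as UTF-8, newline-terminated CSV with a fixed column order."""
    df = pd.DataFrame([{c: getattr(r, c) for c in VIAL_COLUMNS} for r in records],
                      columns=list(VIAL_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_mi_records(path: str | Path,
                    schema_map: Mapping[str, str] | None = None) -> list[MIRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _apply_schema_map(df, MI_COLUMNS, schema_map)
    has_block = "block" in df.columns
    out: list[MIRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(MIRecord(
                group_id=str(getattr(row, "group_id")),
                unit_id=str(getattr(row, "unit_id")),
                mi=float(getattr(row, "mi")),
                n_hit=_int_cell(getattr(row, "n_hit"), i, "n_hit"),
                n_sham=_int_cell(getattr(row, "n_sham"), i, "n_sham"),
                baseline_mode=str(getattr(row, "baseline_mode")).strip().lower(),
                block=str(getattr(row, "block")) if has_block else "",
            ))
        except (ValidationError, ValueError) as err:
            if isinstance(err, ValidationError):
                raise ValidationError(f"row {i}: {err}") from None
            raise ValidationError(f"row {i}: non-numeric mi value") from None
    return out


def write_mi_records(records: Iterable[MIRecord], path: str | Path) -> None:
    cols = list(MI_COLUMNS) + ["block"]
    df = pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_masses(path: str | Path,
                schema_map: Mapping[str, str] | None = None) -> list[MassRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = _apply_schema_map(df, MASS_COLUMNS, schema_map)
    out: list[MassRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = getattr(row, "dry_mass")
        try:
            mass = float(raw)
        except ValueError:
            raise ValidationError(f"row {i}: non-numeric dry_mass {raw!r}") from None
        try:
            out.append(MassRecord(group_id=str(getattr(row, "group_id")),
                                  sex=str(getattr(row, "sex")).strip().lower(),
                                  dry_mass=mass))
        except ValidationError as err:
            raise ValidationError(f"row {i}: {err}") from None
    return out


def write_masses(records: Iterable[MassRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in MASS_COLUMNS} for r in records],
                      columns=list(MASS_COLUMNS))
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def read_line_traits(path: str | Path,
                     schema_map: Mapping[str, str] | None = None) -> LineTraitTable:
    df = pd.read_csv(path)
    df = _apply_schema_map(df, ("line_id",), schema_map)
    return LineTraitTable(df)


def write_line_traits(table: LineTraitTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
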