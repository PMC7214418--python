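"""Measurement table, analyte panel, validation and log-space transforms.

The central object is :class:`SingleCellTable`, an ``m x n`` matrix of
strictly positive single-cell analyte levels (fluorescence-derived arbitrary
units) together with a per-cell ordinal day label.  All downstream stages
(surprisal decomposition, graph building, clustering, criticality, networks)
operate on the natural-log transform of this table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Input data violates a structural invariant."""


class ParseError(ValidationError):
    """A file could not be parsed into a valid table."""


#: The six functional marker categories.
CATEGORIES = (
    "metabolic regulator",
    "metabolic enzyme/uptake",
    "signaling phosphoprotein",
    "proliferation/cell-state marker",
    "resistance marker",
    "transcription factor",
)

#: Category catalog for the default 20-analyte panel.
DEFAULT_CATEGORIES: dict[str, str] = {
    "Ki67": "proliferation/cell-state marker",
    "MART1": "proliferation/cell-state marker",
    "MITF": "transcription factor",
    "Slug": "transcription factor",
    "PFK": "metabolic enzyme/uptake",
    "PKM2": "metabolic enzyme/uptake",
    "LDH": "metabolic enzyme/uptake",
    "GlucoseUptake": "metabolic enzyme/uptake",
    "HIF1a": "metabolic regulator",
    "p-AMPKa": "metabolic regulator",
    "p-LKB": "metabolic regulator",
    "p-ACAC": "metabolic regulator",
    "p-ERK": "signaling phosphoprotein",
    "p-NFkB-p65": "signaling phosphoprotein",
    "p-S6": "signaling phosphoprotein",
    "p-mTOR": "signaling phosphoprotein",
    "TNFR": "resistance marker",
    "N-cadherin": "resistance marker",
    "NGFR": "resistance marker",
    "AXL": "resistance marker",
}

#: Marker subset used for per-day clustering (and, by default, for the
#: criticality indices): proliferation, lineage and metabolic-stress markers.
CLUSTERING_MARKERS = (
    "Ki67",
    "MART1",
    "HIF1a",
    "LDH",
    "p-AMPKa",
    "p-ERK",
    "PFK",
    "p-ACAC",
    "Slug",
    "p-LKB",
)

DEFAULT_DAYS = (0, 1, 3, 5)


@dataclass(frozen=True)
class AnalytePanel:
    """Ordered analyte identifiers with one functional category each."""

    names: tuple[str, ...]
    category: Mapping[str, str]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ValidationError("panel must contain at least one analyte")
        if len(set(names)) != len(names):
            raise ValidationError("analyte names must be unique")
        for name in names:
            cat = self.category.get(name)
            if cat is None:
                raise ValidationError(f"analyte {name!r} has no category")
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"analyte {name!r} has unknown category {cat!r}"
                )

    @classmethod
    def from_names(
        cls, names: Sequence[str], default_category: str | None = None
    ) -> "AnalytePanel":
        """Build a panel by looking names up in the default catalog.

        Unknown analytes take ``default_category`` if given, otherwise raise.
        """
        category: dict[str, str] = {}
        for name in names:
            if name in DEFAULT_CATEGORIES:
                category[name] = DEFAULT_CATEGORIES[name]
            elif default_category is not None:
                category[name] = default_category
            else:
                raise ValidationError(
                    f"analyte {name!r} is not in the default catalog; "
                    "pass an explicit panel or default_category"
                )
        return cls(names=tuple(names), category=category)

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        """Column indices of ``names`` in panel order."""
        pos = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ValidationError(f"analytes not in panel: {missing}")
        return np.array([pos[n] for n in names], dtype=int)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class SingleCellTable:
    """``m`` cells x ``n`` analytes with per-cell day labels.

    Values are strictly positive linear fluorescence levels unless
    ``log_space`` is set, in which case they are natural-log levels.
    """

    values: np.ndarray
    cell_ids: tuple[str, ...]
    day: np.ndarray
    panel: AnalytePanel
    log_space: bool = False
    day_levels: tuple[int, ...] = DEFAULT_DAYS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = tuple(str(c) for c in self.cell_ids)
        self.day = np.asarray(self.day, dtype=int)
        self.day_levels = tuple(int(d) for d in self.day_levels)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        m, n = self.values.shape if self.values.ndim == 2 else (0, 0)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if m != len(self.cell_ids):
            raise ValidationError(
                f"{m} rows but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if n != len(self.panel):
            raise ValidationError(
                f"{n} columns but panel has {len(self.panel)} analytes"
            )
        if self.day.shape != (m,):
            raise ValidationError("day labels must be one per cell")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain NaN or infinities")
        if not self.log_space and np.any(self.values <= 0):
            bad = int(np.sum(self.values <= 0))
            raise ValidationError(
                f"{bad} nonpositive values in linear-space table "
                "(configure a floor or clean the input)"
            )
        if len(set(self.day_levels)) != len(self.day_levels):
            raise ValidationError("day_levels must be unique")
        extra = set(self.day.tolist()) - set(self.day_levels)
        if extra:
            raise ValidationError(
                f"day labels {sorted(extra)} outside declared levels "
                f"{self.day_levels}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def analytes(self) -> tuple[str, ...]:
        return self.panel.names

    def days_present(self) -> list[int]:
        """Days with at least one cell, in declared order."""
        present = set(self.day.tolist())
        return [d for d in self.day_levels if d in present]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.panel.index_of([name])[0]]

    def subset(self, mask: np.ndarray) -> "SingleCellTable":
        """Row subset; column order and panel are preserved."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return dataclasses.replace(
            self,
            values=self.values[idx],
            cell_ids=tuple(self.cell_ids[i] for i in idx),
            day=self.day[idx],
        )

    def marker_matrix(self, markers: Sequence[str] | None = None) -> np.ndarray:
        """Value submatrix for ``markers`` (panel order preserved otherwise)."""
        if markers is None:
            return self.values
        return self.values[:, self.panel.index_of(markers)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.panel.names))
        df.insert(0, "day", self.day)
        df.insert(0, "cell_id", list(self.cell_ids))
        return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(
    path,
    day_column: str = "day",
    panel: AnalytePanel | None = None,
    floor: float | None = None,
    cell_id_column: str = "cell_id",
    day_levels: Sequence[int] = DEFAULT_DAYS,
    default_category: str | None = None,
) -> SingleCellTable:
    """Read a validated linear-space table from CSV.

    The CSV must have a header; one column carries the day label, an optional
    ``cell_id`` column carries identifiers (generated as ``cell0..`` when
    absent) and every remaining column is a numeric analyte level.  Column
    order defines analyte order.  ``floor`` clamps nonpositive levels to a
    small positive value before validation; without it any nonpositive value
    is rejected.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot read CSV {path}: {exc}") from exc
    if day_column not in df.columns:
        raise ParseError(f"no day column {day_column!r} in {path}")
    day = df[day_column].to_numpy()
    if cell_id_column in df.columns:
        cell_ids = [str(c) for c in df[cell_id_column]]
    else:
        cell_ids = [f"cell{i}" for i in range(len(df))]
    analyte_cols = [
        c for c in df.columns if c not in (day_column, cell_id_column)
    ]
    values = np.empty((len(df), len(analyte_cols)), dtype=float)
    for j, col in enumerate(analyte_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value in column {col!r}, row {row}: "
                f"{df[col].iloc[row]!r}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ParseError(f"missing value in column {col!r}, row {row}")
        values[:, j] = numeric.to_numpy()
    if floor is not None:
        if floor <= 0:
            raise ValidationError("floor must be positive")
        values = np.maximum(values, floor)
    if panel is None:
        panel = AnalytePanel.from_names(analyte_cols, default_category)
    elif tuple(panel.names) != tuple(analyte_cols):
        raise ValidationError(
            "CSV columns do not match the supplied panel (order matters)"
        )
    return SingleCellTable(
        values=values,
        cell_ids=tuple(cell_ids),
        day=day,
        panel=panel,
        log_space=False,
        day_levels=tuple(day_levels),
    )


def write_table(table: SingleCellTable, path) -> None:
    """Write a table to CSV (cell_id, day, then analytes in panel order)."""
    table.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def log_transform(
    table: SingleCellTable, floor: float | None = None
) -> SingleCellTable:
    """Natural-log transform of a linear-space table.

    ``floor`` clamps values to a positive minimum first; without it any
    nonpositive value is an error (linear-space validation already enforces
    positivity on construction, so the floor mainly matters when callers
    bypass the constructor checks).
    """
    if table.log_space:
        raise ValidationError("table is already in log space")
    values = table.values
    if floor is not None:
        if floor <= 0:
            raise ValidationError("floor must be positive")
        values = np.maximum(values, floor)
    if np.any(values <= 0):
        raise ValidationError("nonpositive values; configure a floor")
    return dataclasses.replace(table, values=np.log(values), log_space=True)


def exp_transform(table: SingleCellTable) -> SingleCellTable:
    """Inverse of :func:`log_transform`."""
    if not table.log_space:
        raise ValidationError("table is not in log space")
    return dataclasses.replace(table, values=np.exp(table.values), log_space=False)


def zscore_normalize(table: SingleCellTable) -> SingleCellTable:
    """Standardize every analyte column to mean 0, population sd 1.

    Optional preprocessing mirroring the robustness check of running the
    decomposition on z-scored log levels.  Requires a log-space table.
    """
    if not table.log_space:
        raise ValidationError("z-scoring expects a log-space table")
    values = table.values
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # population sd
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [table.panel.names[j] for j in zero]
        raise ValidationError(f"zero-variance analytes: {names}")
    return dataclasses.replace(table, values=(values - mean) / sd)
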