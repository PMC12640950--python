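"""Cytometry event tables: I/O, arcsinh transformation, threshold gating.

An *event table* holds one row per detected cell: sample metadata (donor,
arm, timepoint, panel) plus one intensity column per marker. Raw
fluorescence intensities are non-negative and heavy-tailed; analysis happens
on the arcsinh scale (``asinh(x / cofactor)``), the standard
variance-stabilising transform for fluorescence cytometry. Gating selects
the analysed compartment (live, lineage-positive, reporter-positive cells)
with ordered threshold clauses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, SchemaError, TransformError

__all__ = [
    "METADATA_COLUMNS",
    "PanelDef",
    "EventTable",
    "GateClause",
    "GateSpec",
    "read_event_table",
    "arcsinh_transform",
    "gate_events",
    "concat_event_tables",
]

logger = logging.getLogger(__name__)

#: Required per-cell metadata columns, in canonical order.
METADATA_COLUMNS = ("donor", "arm", "timepoint", "panel")


@dataclass(frozen=True)
class PanelDef:
    """A staining panel: ordered marker names with optional role tags.

    Roles are ``"phenotype"`` (default), ``"lineage"`` or ``"viability"``.
    At least two phenotype markers are required for downstream clustering.
    """

    panel_id: str
    markers: tuple[str, ...]
    roles: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ConfigError(f"panel {self.panel_id!r}: duplicate marker names")
        for m, r in self.roles.items():
            if m not in self.markers:
                raise ConfigError(f"panel {self.panel_id!r}: role for unknown marker {m!r}")
            if r not in ("phenotype", "lineage", "viability"):
                raise ConfigError(f"panel {self.panel_id!r}: unknown role {r!r}")
        if len(self.phenotype_markers) < 2:
            raise ConfigError(f"panel {self.panel_id!r}: need >= 2 phenotype markers")

    @property
    def phenotype_markers(self) -> tuple[str, ...]:
        return tuple(m for m in self.markers if self.roles.get(m, "phenotype") == "phenotype")

    @property
    def viability_marker(self) -> str | None:
        for m in self.markers:
            if self.roles.get(m) == "viability":
                return m
        return None


@dataclass
class EventTable:
    """Per-cell marker intensities plus complete sample metadata.

    ``data`` holds the metadata columns, the marker columns and any extra
    annotation columns (e.g. the synthetic generator's ``true_population``).
    ``transformed`` records whether intensities are on the arcsinh scale;
    ``cofactor`` is kept so the transform stays invertible.
    """

    data: pd.DataFrame
    markers: tuple[str, ...]
    transformed: bool = False
    cofactor: float | None = None

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ConfigError("marker names must be unique")
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing metadata column(s): {missing}")
        missing = [m for m in self.markers if m not in self.data.columns]
        if missing:
            raise SchemaError(f"missing marker column(s): {missing}")
        meta = self.data[list(METADATA_COLUMNS)]
        if meta.isna().any().any():
            raise SchemaError("incomplete sample metadata")
        mat = self.data[list(self.markers)]
        if mat.isna().any().any():
            rows = list(mat.index[mat.isna().any(axis=1)][:5])
            raise ParseError(f"missing marker value(s), first at row(s) {rows}")
        if not all(np.issubdtype(dt, np.number) for dt in mat.dtypes):
            raise ParseError("non-numeric marker column(s)")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def marker_matrix(self) -> np.ndarray:
        """Cells x markers intensity matrix (float64 copy)."""
        return self.data[list(self.markers)].to_numpy(dtype=float)

    def sample_key(self) -> pd.DataFrame:
        return self.data[list(METADATA_COLUMNS)]


Direction = Literal["above", "below"]


@dataclass(frozen=True)
class GateClause:
    marker: str
    direction: Direction
    threshold: float

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ConfigError(f"gate direction must be 'above' or 'below', got {self.direction!r}")
        if not math.isfinite(self.threshold):
            raise ConfigError(f"gate threshold for {self.marker!r} must be finite")


@dataclass(frozen=True)
class GateSpec:
    """Ordered conjunction of threshold clauses on the transformed scale."""

    clauses: tuple[GateClause, ...]

    @classmethod
    def from_tuples(cls, items: Iterable[tuple[str, str, float]]) -> "GateSpec":
        return cls(tuple(GateClause(m, d, float(t)) for m, d, t in items))


def read_event_table(path: str | Path, panel: PanelDef) -> EventTable:
    """Load an event table from CSV (``.csv``) or TSV (anything else).

    Validates the header against the panel and the metadata schema, and
    reports the first non-numeric or empty marker cell with its row index.
    Row order is preserved.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing metadata column {col!r}")
    for marker in panel.markers:
        if marker not in df.columns:
            raise SchemaError(f"{path.name}: missing marker column {marker!r}")
    for marker in panel.markers:
        col = pd.to_numeric(df[marker], errors="coerce")
        bad = col.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path.name}: non-numeric or empty value for {marker!r} at row {row}")
        df[marker] = col.astype(float)
    return EventTable(df, tuple(panel.markers), transformed=False)


def arcsinh_transform(table: EventTable, cofactor: float = 150.0) -> EventTable:
    """Return a new table with every marker value replaced by asinh(x / cofactor).

    The default cofactor of 150 is conventional for fluorescence flow
    cytometry. Re-transforming an already-transformed table is an error.
    """
    if cofactor <= 0:
        raise ConfigError("cofactor must be positive")
    if table.transformed:
        raise TransformError("event table is already on the arcsinh scale")
    data = table.data.copy()
    data[list(table.markers)] = np.arcsinh(data[list(table.markers)].to_numpy(dtype=float) / cofactor)
    return EventTable(data, table.markers, transformed=True, cofactor=cofactor)


def inverse_transform(table: EventTable) -> EventTable:
    """Undo :func:`arcsinh_transform` (``sinh(y) * cofactor``)."""
    if not table.transformed or table.cofactor is None:
        raise TransformError("table is not arcsinh-transformed")
    data = table.data.copy()
    data[list(table.markers)] = np.sinh(data[list(table.markers)].to_numpy(dtype=float)) * table.cofactor
    return EventTable(data, table.markers, transformed=False, cofactor=None)


def gate_events(table: EventTable, gate: GateSpec) -> EventTable:
    """Retain exactly the cells satisfying every clause (strict inequalities).

    Metadata is unchanged; the retained fraction is logged. An all-excluding
    gate yields an empty table with a warning rather than an error.
    """
    if not table.transformed:
        raise TransformError("gate thresholds are defined on the transformed scale")
    mask = np.ones(table.n_cells, dtype=bool)
    for clause in gate.clauses:
        if clause.marker not in table.markers:
            raise SchemaError(f"gate on unknown marker {clause.marker!r}")
        values = table.data[clause.marker].to_numpy(dtype=float)
        if clause.direction == "above":
            mask &= values > clause.threshold
        else:
            mask &= values < clause.threshold
    kept = int(mask.sum())
    frac = kept / table.n_cells if table.n_cells else 0.0
    logger.info("gate retained %d/%d cells (%.1f%%)", kept, table.n_cells, 100 * frac)
    if kept == 0:
        warnings.warn("gate retained zero cells", stacklevel=2)
    data = table.data.loc[mask].reset_index(drop=True)
    return EventTable(data, table.markers, transformed=True, cofactor=table.cofactor)


def concat_event_tables(tables: Sequence[EventTable]) -> EventTable:
    """Pool several event tables (same panel, same transform state)."""
    if not tables:
        raise ConfigError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.markers != first.markers:
            raise ConfigError("tables have different marker panels")
        if t.transformed != first.transformed:
            raise ConfigError("tables mix transformed and raw intensities")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return EventTable(data, first.markers, transformed=first.transformed, cofactor=first.cofactor)
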