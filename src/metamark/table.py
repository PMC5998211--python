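"""Feature-table container and CSV round-trip.

A feature table holds one intensity value per sample and marker together
with per-sample group and batch labels.  The on-disk format is a plain CSV
with mandatory header ``sample_id, group, batch, <marker_1>, ...``; group
labels are ``case``/``control`` (the aliases ``OC`` and ``CNTRL`` are
accepted on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ClassDegeneracyError, ParseError

CASE = "case"
CONTROL = "control"
GROUP_ALIASES = {
    "case": CASE,
    "oc": CASE,
    "eoc": CASE,
    "control": CONTROL,
    "cntrl": CONTROL,
    "ctrl": CONTROL,
}

_META_COLUMNS = ("sample_id", "group", "batch")


@dataclass
class FeatureTable:
    """Samples x markers intensity matrix with group and batch labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique per-sample identifiers; one per row of ``intensities``.
    groups : sequence of str
        Per-sample class label, ``"case"`` or ``"control"``.
    batches : sequence of str
        Per-sample analytical-batch identifier.
    markers : sequence of str
        Unique marker names; one per column of ``intensities``.
    intensities : ndarray
        Two-dimensional float array, shape ``(n_samples, n_markers)``.
    """

    sample_ids: list[str]
    groups: np.ndarray
    batches: np.ndarray
    markers: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.markers = [str(m) for m in self.markers]
        self.groups = np.asarray(self.groups, dtype=object)
        self.batches = np.asarray(self.batches, dtype=object)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, p = self.intensities.shape
        if len(self.sample_ids) != n or len(self.groups) != n or len(self.batches) != n:
            raise ParseError(
                f"row mismatch: {n} intensity rows but "
                f"{len(self.sample_ids)} sample ids, {len(self.groups)} groups, "
                f"{len(self.batches)} batches"
            )
        if len(self.markers) != p:
            raise ParseError(f"column mismatch: {p} columns but {len(self.markers)} marker names")
        dup = _duplicates(self.markers)
        if dup:
            raise ParseError(f"duplicate marker names: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ParseError(f"duplicate sample ids: {sorted(dup)}")
        bad = set(self.groups) - {CASE, CONTROL}
        if bad:
            raise ParseError(f"unknown group labels: {sorted(bad)}; expected case/control")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_markers(self) -> int:
        return self.intensities.shape[1]

    def is_case(self) -> np.ndarray:
        """Boolean mask of case samples."""
        return self.groups == CASE

    def require_two_classes(self) -> None:
        if len(set(self.groups)) < 2:
            raise ClassDegeneracyError("both case and control samples are required")

    def with_intensities(self, values: np.ndarray) -> "FeatureTable":
        """Copy of the table with a replaced intensity matrix (same shape)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.intensities.shape:
            raise ValueError(f"shape {values.shape} != {self.intensities.shape}")
        return replace(self, intensities=values)

    def marker_values(self, marker: str) -> np.ndarray:
        return self.intensities[:, self.markers.index(marker)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.markers)
        df.insert(0, "batch", self.batches)
        df.insert(0, "group", self.groups)
        df.insert(0, "sample_id", self.sample_ids)
        return df


@dataclass
class ProcessedTable:
    """A feature table after preprocessing, with an append-only step record.

    ``constants`` holds the per-marker statistics of each applied step
    (batch RMS divisors, pareto centering/scaling constants, zero-variance
    flags).  ``unscaled`` keeps a snapshot of the matrix before pareto
    scaling so group means stay interpretable for direction calls.
    """

    table: FeatureTable
    steps: list[str] = field(default_factory=list)
    constants: dict = field(default_factory=dict)
    unscaled: np.ndarray | None = None

    # passthrough so processed tables can be consumed wherever a feature
    # table is expected
    @property
    def sample_ids(self) -> list[str]:
        return self.table.sample_ids

    @property
    def groups(self) -> np.ndarray:
        return self.table.groups

    @property
    def batches(self) -> np.ndarray:
        return self.table.batches

    @property
    def markers(self) -> list[str]:
        return self.table.markers

    @property
    def intensities(self) -> np.ndarray:
        return self.table.intensities

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    @property
    def n_markers(self) -> int:
        return self.table.n_markers

    def is_case(self) -> np.ndarray:
        return self.table.is_case()

    def require_two_classes(self) -> None:
        self.table.require_two_classes()


def _duplicates(names: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for name in names:
        (dup if name in seen else seen).add(name)
    return dup


def read_feature_table(path: str | Path, *, require_nonnegative: bool = True) -> FeatureTable:
    """Read a feature table from CSV.

    Raises :class:`ParseError` on missing metadata columns, duplicate
    sample ids or marker names, non-numeric intensity cells, or (by
    default) negative intensities.  Group aliases ``OC``/``CNTRL`` are
    mapped to ``case``/``control``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, dtype={"sample_id": str, "batch": str}, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing mandatory column '{col}'")
    markers = [c for c in df.columns if c not in _META_COLUMNS]
    if not markers:
        raise ParseError(f"{path}: no marker columns found")
    values = df[markers].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise ParseError(
            f"{path}: non-numeric intensity for sample "
            f"'{df['sample_id'].iloc[i]}', marker '{markers[j]}' (data line {i + 2})"
        )
    if require_nonnegative and (values < 0).any():
        i, j = map(int, np.argwhere(values < 0)[0])
        raise ParseError(
            f"{path}: negative intensity for sample "
            f"'{df['sample_id'].iloc[i]}', marker '{markers[j]}'"
        )
    groups = []
    for raw in df["group"]:
        key = str(raw).strip().lower()
        if key not in GROUP_ALIASES:
            raise ParseError(f"{path}: unknown group label '{raw}'")
        groups.append(GROUP_ALIASES[key])
    return FeatureTable(
        sample_ids=list(df["sample_id"]),
        groups=np.array(groups, dtype=object),
        batches=np.array([str(b) for b in df["batch"]], dtype=object),
        markers=markers,
        intensities=values,
    )


def write_feature_table(table: FeatureTable | ProcessedTable, path: str | Path) -> None:
    """Write a feature table as CSV with full float precision."""
    inner = table.table if isinstance(table, ProcessedTable) else table
    df = inner.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")
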