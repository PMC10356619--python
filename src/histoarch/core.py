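"""Core in-memory containers: cell maps and per-cell label assignments.

A :class:`CellMap` holds one imaged tissue section as a cell table (one row
per segmented cell: coordinates, cell type, sample/donor/region metadata)
plus the section area used as the denominator of density statistics.  A
:class:`LabelAssignment` attaches one structural label per cell at a given
level of the tissue hierarchy (cell_type, neighbourhood, community or
tissue_unit), aligned positionally with the CellMap's rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import IntegrityError

__all__ = ["CellMap", "LabelAssignment", "CELL_COLUMNS", "OPTIONAL_COLUMNS"]

CELL_COLUMNS = ("cell_id", "x", "y", "cell_type", "sample_id")
OPTIONAL_COLUMNS = ("donor_id", "region", "group", "compartment")


@dataclass
class CellMap:
    """One imaged section's cells plus its total area.

    Parameters
    ----------
    cells
        DataFrame with columns ``cell_id, x, y, cell_type, sample_id``
        (plus optional ``donor_id, region, group, compartment``).  Exactly
        one distinct ``sample_id`` per CellMap.
    area
        Section area in squared length units; used by the same-cell density
        score and never inferred here (io reads compute a convex-hull area
        when the caller does not supply one).
    """

    cells: pd.DataFrame
    area: float

    def __post_init__(self) -> None:
        df = self.cells
        missing = [c for c in CELL_COLUMNS if c not in df.columns]
        if missing:
            raise IntegrityError(f"CellMap missing columns: {missing}")
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df = df.copy()
                df[col] = "unknown"
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise IntegrityError(f"duplicate cell_id {dup!r} in CellMap")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise IntegrityError("non-finite coordinates in CellMap")
        if df["sample_id"].nunique() != 1:
            raise IntegrityError("a CellMap must contain exactly one sample_id")
        if (df["cell_type"].astype(str) == "").any():
            raise IntegrityError("empty cell_type in CellMap")
        if not (float(self.area) > 0):
            raise IntegrityError(f"area must be > 0, got {self.area}")
        self.cells = df.reset_index(drop=True)
        self.area = float(self.area)

    # -- convenience accessors -------------------------------------------
    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def sample_id(self) -> str:
        return str(self.cells["sample_id"].iloc[0])

    @property
    def group(self) -> str:
        return str(self.cells["group"].iloc[0])

    @property
    def donor_id(self) -> str:
        return str(self.cells["donor_id"].iloc[0])

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    @property
    def cell_types(self) -> np.ndarray:
        return self.cells["cell_type"].to_numpy(dtype=object)

    def type_labels(self) -> "LabelAssignment":
        """The cell_type column viewed as the lowest-level label assignment."""
        return LabelAssignment(level="cell_type", labels=self.cell_types.copy())


@dataclass
class LabelAssignment:
    """Per-cell labels at one structural level, aligned with a CellMap."""

    level: str
    labels: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=object)
        if labels.ndim != 1:
            raise IntegrityError("labels must be one-dimensional")
        if any(l is None or str(l) == "" for l in labels):
            raise IntegrityError("every cell must carry a non-empty label")
        self.labels = labels

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_set(self) -> list:
        return sorted(set(self.labels))

    def relabel(self, mapping: Mapping[str, str], level: str | None = None) -> "LabelAssignment":
        missing = sorted(set(self.labels) - set(mapping))
        if missing:
            raise IntegrityError(f"mapping does not cover labels: {missing}")
        new = np.array([mapping[l] for l in self.labels], dtype=object)
        return LabelAssignment(level=level or self.level, labels=new,
                               meta={**dict(self.meta), "merged_from": self.level})


def concat_labels(assignments: Sequence[LabelAssignment]) -> LabelAssignment:
    """Concatenate per-sample assignments of the same level (cohort order)."""
    levels = {a.level for a in assignments}
    if len(levels) != 1:
        raise IntegrityError(f"cannot concatenate assignments of levels {sorted(levels)}")
    labels = np.concatenate([a.labels for a in assignments])
    return LabelAssignment(level=assignments[0].level, labels=labels)
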