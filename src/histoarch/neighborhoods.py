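"""Multicellular neighbourhood discovery from kNN composition windows.

The window of a cell is the cell plus its k-1 nearest neighbours (total k,
default 10; whether the index cell is included is configurable).  Each
window is summarised as the fraction of each label (cell type at the lowest
level) it contains; k-means overclusters these composition vectors (default
30 clusters) and clusters are merged into named structures via an explicit
user-supplied mapping, guided by label-by-cell-type fold-enrichment
matrices.  Conservation between anatomical groups is the difference of the
two groups' enrichment matrices, ordered by total absolute difference.
Concentric profiles report composition and enrichment in growing disks (or
annuli) around an anchor cell type, e.g. Paneth-like crypt anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from ._knn import knn_window
from .core import CellMap, LabelAssignment
from .exceptions import ConfigError, IntegrityError

__all__ = [
    "WindowMatrix", "EnrichmentMatrix", "ConcentricProfile",
    "composition_windows", "cluster_windows", "merge_clusters",
    "enrichment_matrix", "conservation_delta", "concentric_enrichment",
    "suggest_merges",
]


@dataclass
class WindowMatrix:
    """Per-cell label fractions within kNN windows (rows sum to 1)."""

    values: pd.DataFrame          # rows = cells (cell_id index), cols = labels
    k: int
    level: str
    include_self: bool = True

    @property
    def n(self) -> int:
        return len(self.values)


def composition_windows(
    cellmap: CellMap,
    labels: LabelAssignment | None = None,
    k: int = 10,
    *,
    include_self: bool = True,
) -> WindowMatrix:
    """Label-composition vectors of the k-cell window around every cell.

    ``labels`` defaults to the cell types.  Windows never cross sample
    boundaries because a CellMap is a single sample.
    """
    if labels is None:
        labels = cellmap.type_labels()
    if len(labels) != cellmap.n:
        raise IntegrityError("label assignment does not cover the cell map")
    idx = knn_window(cellmap.coords, k, include_self=include_self)
    cats = sorted(set(labels.labels))
    code_of = {c: i for i, c in enumerate(cats)}
    codes = np.array([code_of[l] for l in labels.labels], dtype=np.intp)
    window_codes = codes[idx]
    counts = np.zeros((cellmap.n, len(cats)))
    np.add.at(counts, (np.arange(cellmap.n)[:, None], window_codes), 1.0)
    values = pd.DataFrame(counts / k, columns=cats,
                          index=pd.Index(cellmap.cells["cell_id"], name="cell_id"))
    return WindowMatrix(values=values, k=k, level=labels.level,
                        include_self=include_self)


def cluster_windows(
    windows: WindowMatrix,
    n_clusters: int,
    seed: int = 0,
    *,
    group_by: Sequence[str] | np.ndarray | None = None,
    level: str = "neighbourhood",
    prefix: str = "c",
) -> LabelAssignment:
    """K-means over window composition vectors (fixed seed, 10 restarts).

    With ``group_by`` (one group name per cell, e.g. region) clustering runs
    independently within each group and labels are prefixed with the group
    name.  Deterministic given the seed.
    """
    X = windows.values.to_numpy(dtype=float)
    n = len(X)
    out = np.empty(n, dtype=object)
    if group_by is None:
        groups = {None: np.arange(n)}
    else:
        group_by = np.asarray(group_by, dtype=object)
        if len(group_by) != n:
            raise ConfigError("group_by must give one group per cell")
        groups = {g: np.flatnonzero(group_by == g) for g in sorted(set(group_by))}
    for g, rows in groups.items():
        if len(rows) == 0:
            raise ConfigError(f"empty group {g!r}")
        sub = X[rows]
        n_distinct = len(np.unique(sub, axis=0))
        if n_clusters > n_distinct:
            raise ConfigError(
                f"n_clusters={n_clusters} exceeds the {n_distinct} distinct "
                f"window vectors" + (f" in group {g!r}" if g is not None else ""))
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        lab = km.fit_predict(sub)
        tag = f"{g}:" if g is not None else ""
        for r, l in zip(rows, lab):
            out[r] = f"{tag}{prefix}{l:02d}"
    return LabelAssignment(level=level, labels=out,
                           meta={"k": windows.k, "n_clusters": n_clusters,
                                 "seed": seed, "per_group": group_by is not None})


def merge_clusters(
    labels: LabelAssignment,
    mapping: Mapping[str, str],
    *,
    level: str | None = None,
) -> LabelAssignment:
    """Relabel clusters through an explicit old_label -> merged_label map."""
    return labels.relabel(mapping, level=level)


@dataclass
class EnrichmentMatrix:
    """Upper-label x lower-label fold enrichment over the overall composition.

    ``matrix[u, c] = frac(c | cells labelled u) / frac(c | all cells)``.
    ``weights`` holds the fraction of all cells carrying each upper label, so
    the cell-weighted column sums of the matrix are exactly 1.
    """

    matrix: pd.DataFrame
    overall: pd.Series
    weights: pd.Series


def enrichment_matrix(
    upper: LabelAssignment, lower: LabelAssignment
) -> EnrichmentMatrix:
    """Fold enrichment of each lower label within each upper label."""
    if len(upper) != len(lower):
        raise IntegrityError("assignments cover different cell sets")
    n = len(upper)
    tab = pd.crosstab(pd.Series(upper.labels, name="upper"),
                      pd.Series(lower.labels, name="lower"))
    tab = tab.sort_index(axis=0).sort_index(axis=1)
    overall = tab.sum(axis=0) / n
    row_frac = tab.div(tab.sum(axis=1), axis=0)
    matrix = row_frac.div(overall, axis=1)
    weights = tab.sum(axis=1) / n
    return EnrichmentMatrix(matrix=matrix, overall=overall, weights=weights)


@dataclass
class ConservationDelta:
    """Difference of two groups' enrichment matrices over shared labels."""

    delta: pd.DataFrame
    row_order: list
    col_order: list


def conservation_delta(
    e_a: EnrichmentMatrix, e_b: EnrichmentMatrix
) -> ConservationDelta:
    """``E_a - E_b`` over the shared labels and cell types, with rows and
    columns ordered by descending total absolute difference (structures and
    types least conserved between groups come first)."""
    rows = e_a.matrix.index.intersection(e_b.matrix.index)
    cols = e_a.matrix.columns.intersection(e_b.matrix.columns)
    if len(rows) == 0 or len(cols) == 0:
        raise IntegrityError("no shared labels between the two enrichment matrices")
    delta = e_a.matrix.loc[rows, cols] - e_b.matrix.loc[rows, cols]
    row_order = delta.abs().sum(axis=1).sort_values(
        ascending=False, kind="stable").index.tolist()
    col_order = delta.abs().sum(axis=0).sort_values(
        ascending=False, kind="stable").index.tolist()
    delta = delta.loc[row_order, col_order]
    return ConservationDelta(delta=delta, row_order=row_order, col_order=col_order)


@dataclass
class ConcentricProfile:
    """Pooled composition/enrichment around anchor cells at growing radii."""

    anchor_type: str
    radii: np.ndarray
    mode: str
    counts: pd.DataFrame       # radius x cell type, pooled over anchors
    composition: pd.DataFrame  # row-normalized counts (NaN when empty)
    enrichment: pd.DataFrame   # composition / overall non-anchor composition


def concentric_enrichment(
    cellmap: CellMap,
    anchor_type: str,
    radii: Sequence[float],
    mode: str = "cumulative_disk",
) -> ConcentricProfile:
    """Cell-type composition around anchor cells at increasing window size.

    For each anchor cell and radius the non-anchor cells within the disk
    (``cumulative_disk``) or annulus (``annulus``) are pooled over anchors;
    enrichment is against the overall non-anchor composition.
    """
    radii = np.asarray(list(radii), dtype=float)
    if len(radii) == 0 or np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ConfigError("radii must be positive and strictly increasing")
    if mode not in ("cumulative_disk", "annulus"):
        raise ConfigError(f"unknown mode {mode!r}")
    types = cellmap.cell_types
    anchors = np.flatnonzero(types == anchor_type)
    if len(anchors) == 0:
        raise ConfigError(f"no cells of anchor type {anchor_type!r}")
    others = np.flatnonzero(types != anchor_type)
    other_types = types[others]
    cats = sorted(set(other_types))
    code_of = {c: i for i, c in enumerate(cats)}
    codes = np.array([code_of[t] for t in other_types], dtype=np.intp)

    tree = cKDTree(cellmap.coords[others])
    cum = np.zeros((len(radii), len(cats)))
    for ri, r in enumerate(radii):
        hits = tree.query_ball_point(cellmap.coords[anchors], r)
        flat = np.concatenate([np.asarray(h, dtype=np.intp) for h in hits]) \
            if any(len(h) for h in hits) else np.empty(0, dtype=np.intp)
        cum[ri] = np.bincount(codes[flat], minlength=len(cats))
    counts = cum if mode == "cumulative_disk" else np.diff(
        np.vstack([np.zeros(len(cats)), cum]), axis=0)
    counts_df = pd.DataFrame(counts, index=pd.Index(radii, name="radius"),
                             columns=cats)
    totals = counts_df.sum(axis=1)
    composition = counts_df.div(totals.where(totals > 0), axis=0)
    overall = pd.Series(np.bincount(codes, minlength=len(cats)) / len(others),
                        index=cats)
    enrichment = composition.div(overall, axis=1)
    return ConcentricProfile(anchor_type=anchor_type, radii=radii, mode=mode,
                             counts=counts_df, composition=composition,
                             enrichment=enrichment)


def suggest_merges(enrich: EnrichmentMatrix, min_corr: float = 0.9) -> list[tuple]:
    """Pairs of labels whose enrichment profiles correlate at >= min_corr —
    merge candidates only; nothing is applied silently."""
    m = enrich.matrix
    out = []
    labels = list(m.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            va, vb = m.loc[a].to_numpy(), m.loc[b].to_numpy()
            if np.ptp(va) == 0 or np.ptp(vb) == 0:
                continue
            r = np.corrcoef(va, vb)[0, 1]
            if r >= min_corr:
                out.append((a, b, float(r)))
    return out
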