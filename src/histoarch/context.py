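"""Spatial-context maps: minimal label combinations covering a cell's window.

For every cell the labels of its k-cell window (k = 100 for neighbourhood
context, 300 for community context) are sorted by descending count; the
minimal prefix whose cumulative fraction reaches the threshold (default
85%) is the cell's spatial-context combination — an unordered label set that
captures interfaces between structures.  Combinations are counted over the
(optionally filtered) cells, rare combinations (frequency below 0.1% by
default) are dropped, and retained combinations are linked into a
containment graph between adjacent cardinalities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._knn import knn_window
from .core import CellMap, LabelAssignment
from .exceptions import ConfigError, IntegrityError

__all__ = ["ContextResult", "context_combinations", "combination_graph"]


@dataclass
class ContextResult:
    """Combination counts plus the per-cell combination assignment."""

    table: pd.DataFrame          # combination (tuple), size, count, frequency
    per_cell: list[tuple]        # one sorted label tuple per (filtered) cell
    n_cells: int
    threshold: float
    k: int


def context_combinations(
    cellmap: CellMap,
    labels: LabelAssignment,
    k: int = 100,
    threshold: float = 0.85,
    *,
    strict: bool = False,
    include_self: bool = True,
    cell_filter: np.ndarray | None = None,
) -> ContextResult:
    """Minimal >= threshold label combinations of each cell's window.

    Labels within a window are ranked by descending count with ties broken
    lexicographically, and the shortest prefix whose cumulative fraction
    reaches the threshold (strictly exceeds it with ``strict=True``) forms
    the cell's combination.  ``cell_filter`` is a boolean mask restricting
    which cells contribute combinations (e.g. mucosa-only); windows are
    still computed over all cells.
    """
    if not (0.0 < threshold < 1.0):
        raise ConfigError("threshold must lie in (0, 1)")
    if len(labels) != cellmap.n:
        raise IntegrityError("label assignment does not cover the cell map")
    idx = knn_window(cellmap.coords, k, include_self=include_self)
    cats = sorted(set(labels.labels))
    code_of = {c: i for i, c in enumerate(cats)}
    codes = np.array([code_of[l] for l in labels.labels], dtype=np.intp)
    counts = np.zeros((cellmap.n, len(cats)), dtype=np.int64)
    np.add.at(counts, (np.arange(cellmap.n)[:, None], codes[idx]), 1)

    if cell_filter is not None:
        cell_filter = np.asarray(cell_filter, dtype=bool)
        if len(cell_filter) != cellmap.n:
            raise ConfigError("cell_filter must give one flag per cell")
        counts = counts[cell_filter]

    # rank labels in each window by descending count, ties by label name
    # (columns are lexicographically sorted, stable sort keeps that order)
    order = np.argsort(-counts, axis=1, kind="stable")
    sorted_counts = np.take_along_axis(counts, order, axis=1)
    cum = np.cumsum(sorted_counts, axis=1)
    cut = threshold * k
    if strict:
        reached = cum > cut + 1e-9
    else:
        reached = cum >= cut - 1e-9
    sizes = reached.argmax(axis=1) + 1

    per_cell = []
    for i in range(len(counts)):
        members = order[i, :sizes[i]]
        per_cell.append(tuple(sorted(cats[m] for m in members)))
    counter = Counter(per_cell)
    n_cells = len(per_cell)
    rows = [{"combination": combo, "size": len(combo), "count": c,
             "frequency": c / n_cells}
            for combo, c in sorted(counter.items())]
    table = pd.DataFrame(rows, columns=["combination", "size", "count", "frequency"])
    table = table.sort_values(["count", "combination"],
                              ascending=[False, True]).reset_index(drop=True)
    return ContextResult(table=table, per_cell=per_cell, n_cells=n_cells,
                         threshold=threshold, k=k)


def combination_graph(result: ContextResult, min_freq: float = 0.001) -> nx.DiGraph:
    """Containment graph over retained combinations.

    Nodes are combinations with frequency strictly above ``min_freq``; an
    edge S -> T exists when S is a subset of T and T has exactly one more
    label.  Node attributes carry count and frequency (drives node size in
    spatial-context plots).
    """
    kept = result.table[result.table["frequency"] > min_freq]
    g = nx.DiGraph()
    for _, row in kept.iterrows():
        g.add_node("+".join(row["combination"]), labels=",".join(row["combination"]),
                   size=int(row["size"]), count=int(row["count"]),
                   frequency=float(row["frequency"]))
    by_size: dict[int, list[tuple]] = {}
    for combo in kept["combination"]:
        by_size.setdefault(len(combo), []).append(combo)
    for s, smaller in sorted(by_size.items()):
        for t in by_size.get(s + 1, []):
            tset = set(t)
            for src in smaller:
                if set(src) <= tset:
                    g.add_edge("+".join(src), "+".join(t))
    return g
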