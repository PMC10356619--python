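"""Deterministic k-nearest-neighbour queries.

All window-based statistics share this helper.  Distances are Euclidean;
exact distance ties are broken by cell index (row order, i.e. cell_id order
after io reads sort by cell_id), so results are reproducible even for maps
with duplicated coordinates.  Small maps use an exact all-pairs computation;
large maps a KD-tree with a tie-aware fallback at the window boundary.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree, distance

from .exceptions import ConfigError

__all__ = ["knn_window", "knn_neighbors"]

_BRUTE_N = 600
_PAD = 8


def _brute_neighbors(coords: np.ndarray, m: int) -> np.ndarray:
    """Exact m nearest others per point, ties by index."""
    n = len(coords)
    d = distance.squareform(distance.pdist(coords))
    np.fill_diagonal(d, np.inf)
    idx = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx, d), axis=1)
    return order[:, :m]


def knn_neighbors(coords: np.ndarray, m: int) -> np.ndarray:
    """Indices of the ``m`` nearest cells to each cell, self excluded.

    Returns an ``(n, m)`` integer array ordered by increasing distance,
    distance ties broken by index.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if m >= n:
        raise ConfigError(f"need m < n neighbours, got m={m}, n={n}")
    if n <= _BRUTE_N:
        return _brute_neighbors(coords, m)

    tree = cKDTree(coords)
    q = min(n, m + 1 + _PAD)
    dist, idx = tree.query(coords, k=q)
    out = np.empty((n, m), dtype=np.intp)
    rows_exact = []
    rows = np.arange(n)
    for i in rows:
        di, ii = dist[i], idx[i]
        keep = ii != i
        di, ii = di[keep], ii[keep]
        order = np.lexsort((ii, di))
        di, ii = di[order], ii[order]
        # a tie group straddling the candidate boundary may hide a
        # lower-index neighbour outside the query; recompute exactly
        if len(di) > m and di[m - 1] == di[-1]:
            rows_exact.append(i)
            continue
        out[i] = ii[:m]
    if rows_exact:
        sub = np.asarray(rows_exact)
        d = distance.cdist(coords[sub], coords)
        d[np.arange(len(sub)), sub] = np.inf
        idx_full = np.broadcast_to(np.arange(n), d.shape)
        order = np.lexsort((idx_full, d), axis=1)
        out[sub] = order[:, :m]
    return out


def knn_window(coords: np.ndarray, k: int, include_self: bool = True) -> np.ndarray:
    """The window of ``k`` cells around each cell.

    With ``include_self`` (the default) the window is the index cell plus its
    ``k - 1`` nearest neighbours; otherwise the ``k`` nearest neighbours.
    Returns an ``(n, k)`` integer index array.
    """
    n = len(coords)
    if k < 1:
        raise ConfigError(f"window size must be >= 1, got {k}")
    if k > n:
        raise ConfigError(f"window size k={k} exceeds the cell count n={n}")
    if include_self:
        if k == 1:
            return np.arange(n, dtype=np.intp)[:, None]
        nb = knn_neighbors(coords, k - 1)
        return np.column_stack([np.arange(n, dtype=np.intp), nb])
    if k == n:
        raise ConfigError("k must be < n when the index cell is excluded")
    return knn_neighbors(coords, k)
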