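"""Tissue motifs: adjacency of contiguous same-label patches tested against
a label-permutation (maximum-entropy) null.

Cell adjacency is a Delaunay triangulation pruned at a maximum edge length
(default 3x the median Delaunay edge).  Instances are connected components
of same-label cells with at least ``min_cells`` members; two instances are
adjacent when any pruned Delaunay edge joins their cells.  The motif
statistic for an unordered label pair {a, b} is the number of adjacent
instance pairs with those labels; the null permutes instance labels
uniformly over the fixed instance graph, preserving the label multiset, and
the one-sided enrichment p-value is (1 + #{null >= observed}) / (n + 1),
Bonferroni-corrected by twice the number of tested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError

from ._knn import knn_neighbors
from .core import CellMap, LabelAssignment
from .exceptions import ConfigError, IntegrityError

__all__ = ["InstanceGraph", "label_instances", "union_graphs", "motif_test"]


@dataclass
class InstanceGraph:
    """Patches of contiguous same-label cells and their adjacency.

    ``labels[i]`` / ``sizes[i]`` describe instance i; ``edges`` is a
    deduplicated (E, 2) array of adjacent instance index pairs (u < v, no
    self loops); ``members`` maps instances to cell ids; ``samples`` records
    provenance.
    """

    labels: np.ndarray
    sizes: np.ndarray
    edges: np.ndarray
    members: list[np.ndarray] = field(default_factory=list)
    samples: tuple[str, ...] = ()

    @property
    def n_instances(self) -> int:
        return len(self.labels)


def _delaunay_edges(coords: np.ndarray) -> np.ndarray:
    tri = Delaunay(coords)
    s = tri.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def cell_adjacency(
    cellmap: CellMap, max_edge: float | None = None
) -> tuple[np.ndarray, float]:
    """Pruned Delaunay cell adjacency; returns (edges, max_edge used).

    Falls back to mutualized 6-nearest-neighbour adjacency (with a warning)
    when the points are degenerate for triangulation.
    """
    coords = cellmap.coords
    try:
        edges = _delaunay_edges(coords)
    except (QhullError, ValueError):
        warnings.warn("degenerate coordinates; falling back to kNN adjacency")
        k = min(6, cellmap.n - 1)
        nb = knn_neighbors(coords, k)
        e = np.column_stack([np.repeat(np.arange(cellmap.n), k), nb.ravel()])
        e.sort(axis=1)
        edges = np.unique(e, axis=0)
    lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
    if max_edge is None:
        max_edge = 3.0 * float(np.median(lengths))
    if not max_edge > 0:
        raise ConfigError("max_edge must be > 0")
    return edges[lengths <= max_edge], float(max_edge)


def label_instances(
    cellmap: CellMap,
    labels: LabelAssignment,
    max_edge: float | None = None,
    min_cells: int = 3,
) -> InstanceGraph:
    """Contiguous same-label patches and the adjacency between them."""
    if len(labels) != cellmap.n:
        raise IntegrityError("label assignment does not cover the cell map")
    if min_cells < 2:
        raise ConfigError("min_cells must be >= 2")
    edges, max_edge = cell_adjacency(cellmap, max_edge)
    lab = labels.labels
    same = lab[edges[:, 0]] == lab[edges[:, 1]]
    se = edges[same]
    n = cellmap.n
    adj = coo_matrix((np.ones(len(se)), (se[:, 0], se[:, 1])), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)

    sizes_all = np.bincount(comp, minlength=n_comp)
    keep = np.flatnonzero(sizes_all >= min_cells)
    inst_of_comp = np.full(n_comp, -1, dtype=np.intp)
    inst_of_comp[keep] = np.arange(len(keep))
    cell_inst = inst_of_comp[comp]

    inst_labels = np.empty(len(keep), dtype=object)
    members: list[np.ndarray] = []
    ids = cellmap.cells["cell_id"].to_numpy(dtype=object)
    for j, c in enumerate(keep):
        cells = np.flatnonzero(comp == c)
        inst_labels[j] = lab[cells[0]]
        members.append(ids[cells])

    iu, iv = cell_inst[edges[:, 0]], cell_inst[edges[:, 1]]
    ok = (iu >= 0) & (iv >= 0) & (iu != iv)
    pe = np.column_stack([iu[ok], iv[ok]])
    pe.sort(axis=1)
    inst_edges = np.unique(pe, axis=0) if len(pe) else np.empty((0, 2), dtype=np.intp)

    return InstanceGraph(labels=inst_labels,
                         sizes=sizes_all[keep].astype(np.intp),
                         edges=inst_edges.astype(np.intp),
                         members=members,
                         samples=(cellmap.sample_id,))


def union_graphs(graphs: Sequence[InstanceGraph]) -> InstanceGraph:
    """Union of the per-region instance graphs of a group (disjoint cells)."""
    seen: set = set()
    for g in graphs:
        cells = {c for m in g.members for c in m}
        if cells & seen:
            raise IntegrityError("cell id collision between instance graphs")
        seen |= cells
    labels, sizes, edges, members, samples = [], [], [], [], []
    offset = 0
    for g in graphs:
        labels.append(g.labels)
        sizes.append(g.sizes)
        if len(g.edges):
            edges.append(g.edges + offset)
        members.extend(g.members)
        samples.extend(g.samples)
        offset += g.n_instances
    return InstanceGraph(
        labels=np.concatenate(labels) if labels else np.empty(0, dtype=object),
        sizes=np.concatenate(sizes) if sizes else np.empty(0, dtype=np.intp),
        edges=np.vstack(edges) if edges else np.empty((0, 2), dtype=np.intp),
        members=members,
        samples=tuple(samples),
    )


def _pair_counts(codes: np.ndarray, edges: np.ndarray, n_labels: int) -> np.ndarray:
    """Counts of adjacent instance pairs per unordered label pair, as a
    condensed vector indexed by a*(n_labels) - a*(a-1)//2 style packing."""
    a = codes[edges[:, 0]]
    b = codes[edges[:, 1]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    flat = lo * n_labels + hi
    return np.bincount(flat, minlength=n_labels * n_labels)


def motif_test(
    graph: InstanceGraph,
    n_permutations: int = 1000,
    seed: int = 0,
    min_instances: int = 5,
    *,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Permutation enrichment test of two-label adjacency motifs.

    Returns one row per unordered label pair with at least one observed
    adjacency: observed count, null mean/sd, empirical p (one-sided
    enrichment by default), Bonferroni-adjusted p (x 2 x number of tested
    pairs, capped at 1) and a tested flag (observed count >=
    ``min_instances``).  The null shuffles instance labels uniformly over
    the fixed graph, preserving the label multiset exactly.
    """
    if n_permutations < 99:
        raise ConfigError("n_permutations must be >= 99")
    cats = sorted(set(graph.labels))
    if len(cats) < 2:
        return pd.DataFrame(columns=["label_a", "label_b", "observed",
                                     "null_mean", "null_sd", "p", "p_adj",
                                     "tested"])
    code_of = {c: i for i, c in enumerate(cats)}
    codes = np.array([code_of[l] for l in graph.labels], dtype=np.intp)
    L = len(cats)
    obs = _pair_counts(codes, graph.edges, L)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, L * L), dtype=np.int64)
    for i in range(n_permutations):
        null[i] = _pair_counts(rng.permutation(codes), graph.edges, L)

    rows = []
    for ai in range(L):
        for bi in range(ai, L):
            flat = ai * L + bi
            o = int(obs[flat])
            if o == 0:
                continue
            nv = null[:, flat]
            ge = int((nv >= o).sum())
            p = (1 + ge) / (n_permutations + 1)
            if two_sided:
                le = int((nv <= o).sum())
                p = min(1.0, 2 * min(p, (1 + le) / (n_permutations + 1)))
            rows.append({"label_a": cats[ai], "label_b": cats[bi],
                         "observed": o, "null_mean": float(nv.mean()),
                         "null_sd": float(nv.std(ddof=0)), "p": p,
                         "tested": o >= min_instances})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        out["p_adj"] = []
        return out
    n_tested = int(out["tested"].sum())
    out["p_adj"] = np.where(out["tested"],
                            np.minimum(1.0, out["p"] * 2 * max(n_tested, 1)),
                            np.nan)
    out.loc[~out["tested"], "p"] = np.nan
    return out.sort_values(["label_a", "label_b"]).reset_index(drop=True)
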