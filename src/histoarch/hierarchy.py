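"""Higher structural levels and the multilevel hierarchy graph.

Communities and tissue units are obtained with exactly the machinery used
for neighbourhoods, but windowing the lower level's labels at a larger
window (defaults 100 and 300) and overclustering with 20 clusters.  The
hierarchy graph connects each label of a level to the labels of the next
level it feeds: an edge to the upper label receiving the largest share of
its cells (reason ``argmax``), and to every upper label of which it makes up
at least 15% of the cells (reason ``threshold``).  Edge weight is the share
of the upper structure composed of the lower label; an alternative
share-of-lower weighting is available by flag.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import CellMap, LabelAssignment
from .exceptions import ConfigError, IntegrityError
from .neighborhoods import cluster_windows, composition_windows

__all__ = ["derive_level", "build_hierarchy_graph"]


def derive_level(
    cellmap: CellMap,
    lower: LabelAssignment,
    k: int = 100,
    n_clusters: int = 20,
    seed: int = 0,
    *,
    level: str = "community",
    include_self: bool = True,
) -> LabelAssignment:
    """Cluster windows of lower-level labels into the next structural level."""
    windows = composition_windows(cellmap, lower, k, include_self=include_self)
    return cluster_windows(windows, n_clusters, seed, level=level,
                           prefix=level[0].upper())


def build_hierarchy_graph(
    levels: Sequence[LabelAssignment],
    threshold: float = 0.15,
    *,
    weight_by: str = "upper",
) -> nx.DiGraph:
    """Directed multilevel graph over consecutive label levels.

    Nodes are ``"level:label"`` with attributes ``level``, ``label`` and
    ``fraction`` (share of all cells).  For consecutive levels an edge
    lower -> upper exists when the upper label receives the largest share of
    the lower label's cells (``reason="argmax"``, ties broken by label name)
    or when the lower label makes up at least ``threshold`` of the upper
    structure (``reason="threshold"``).  ``weight`` is the share of the upper
    structure made of the lower label (``weight_by="upper"``) or the share of
    the lower label's cells going to the upper one (``weight_by="lower"``).
    """
    if len(levels) < 2:
        raise ConfigError("need at least two levels")
    if weight_by not in ("upper", "lower"):
        raise ConfigError(f"unknown weight_by {weight_by!r}")
    n = len(levels[0])
    if any(len(l) != n for l in levels):
        raise IntegrityError("levels cover different cell sets")

    g = nx.DiGraph()
    for lv in levels:
        counts = pd.Series(lv.labels).value_counts()
        for label in sorted(counts.index):
            g.add_node(f"{lv.level}:{label}", level=lv.level, label=str(label),
                       fraction=float(counts[label] / n))

    for lo, up in zip(levels, levels[1:]):
        joint = pd.crosstab(pd.Series(lo.labels, name="lower"),
                            pd.Series(up.labels, name="upper"))
        joint = joint.sort_index(axis=0).sort_index(axis=1)
        n_up = joint.sum(axis=0)
        n_lo = joint.sum(axis=1)
        for l in joint.index:
            row = joint.loc[l]
            best = row.index[np.lexsort((row.index, -row.to_numpy()))[0]]
            for u in joint.columns:
                c = int(joint.at[l, u])
                if c == 0:
                    continue
                share_upper = c / float(n_up[u])
                share_lower = c / float(n_lo[l])
                is_argmax = u == best
                passes = share_upper >= threshold
                if not (is_argmax or passes):
                    continue
                g.add_edge(
                    f"{lo.level}:{l}", f"{up.level}:{u}",
                    weight=share_upper if weight_by == "upper" else share_lower,
                    share_upper=share_upper, share_lower=share_lower,
                    reason="argmax" if is_argmax else "threshold",
                )
    return g
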