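"""Cell-type composition normalization, group tests, same-cell density and
covariate correlation.

The same-cell density score of a cell is its mean Euclidean distance to its
k (default 5) nearest same-type neighbours divided by the maximal-dispersion
spacing ``sqrt(area / N_t)`` — the mean spacing of a grid-like arrangement of
the ``N_t`` cells of that type over the section.  Scores near 0 mean tight
aggregation; scores near 1 mean the type is close to maximally dispersed.
Scores are not clipped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._knn import knn_neighbors
from .core import CellMap
from .exceptions import ConfigError, IntegrityError

__all__ = [
    "compartment_percentages", "compare_groups", "same_cell_density",
    "correlate_with_covariate",
]


def compartment_percentages(
    cellmaps: Sequence[CellMap],
    category_map: Mapping[str, str] | pd.Series | None = None,
    *,
    unmapped: str = "error",
) -> pd.DataFrame:
    """Per-sample cell-type percentages normalized within cell categories.

    For every sample and category (e.g. epithelial / immune / stromal) the
    percentage of each cell type among cells of that category is reported,
    plus an unnormalized table over all cells under the pseudo-category
    ``"all"``.  Percentages within each (sample, category) sum to 100.

    Parameters
    ----------
    category_map
        Mapping cell_type -> category.  ``None`` produces only the "all"
        table.  With ``unmapped="unassigned"`` missing types fall into an
        "unassigned" category instead of raising.
    """
    if isinstance(category_map, pd.Series):
        category_map = category_map.to_dict()
    rows = []
    for cm in cellmaps:
        df = cm.cells
        meta = dict(sample_id=cm.sample_id, donor_id=cm.donor_id,
                    region=str(df["region"].iloc[0]), group=cm.group)
        if category_map is not None:
            missing = sorted(set(df["cell_type"]) - set(category_map))
            if missing and unmapped == "error":
                raise IntegrityError(
                    f"cell types missing from category map: {missing}")
            cat = df["cell_type"].map(lambda t: category_map.get(t, "unassigned"))
        else:
            cat = pd.Series("all", index=df.index)
        work = df.assign(category=cat)
        groups = [work.assign(category="all")]
        if category_map is not None:
            groups.append(work)
        for w in groups:
            counts = (w.groupby(["category", "cell_type"], sort=True)
                      .size().rename("n_cells").reset_index())
            totals = counts.groupby("category")["n_cells"].transform("sum")
            counts["percentage"] = 100.0 * counts["n_cells"] / totals
            for _, r in counts.iterrows():
                rows.append({**meta, "category": r["category"],
                             "cell_type": r["cell_type"],
                             "percentage": r["percentage"],
                             "n_cells": int(r["n_cells"])})
    out = pd.DataFrame(rows).drop_duplicates(
        subset=["sample_id", "category", "cell_type"])
    return out.sort_values(["sample_id", "category", "cell_type"]).reset_index(drop=True)


def compare_groups(
    values: pd.DataFrame,
    *,
    key: str = "cell_type",
    value: str = "percentage",
    group: str = "group",
    groups: tuple[str, str] = ("SB", "CL"),
) -> pd.DataFrame:
    """Welch two-sided t-test per key comparing the two groups.

    ``values`` holds one observation per (donor or sample) x key, e.g. the
    per-donor composition table.  Raw p-values are reported (matching
    unadjusted per-type asterisks) together with Benjamini-Hochberg adjusted
    p-values across keys.  Keys with fewer than two observations in either
    group are flagged untested.
    """
    g1, g2 = groups
    rows = []
    for k, sub in values.groupby(key, sort=True):
        a = sub.loc[sub[group] == g1, value].to_numpy(dtype=float)
        b = sub.loc[sub[group] == g2, value].to_numpy(dtype=float)
        row = {key: k, f"mean_{g1}": a.mean() if len(a) else np.nan,
               f"mean_{g2}": b.mean() if len(b) else np.nan,
               "n_" + g1: len(a), "n_" + g2: len(b)}
        if len(a) < 2 or len(b) < 2:
            row.update(t=np.nan, p=np.nan, tested=False)
        elif np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            row.update(t=0.0, p=1.0, tested=True)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            row.update(t=float(t), p=float(p), tested=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = out["tested"] & out["p"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh")[1]
    return out


@dataclass
class DensityResult:
    """Per-type same-cell density scores for one sample; ``per_cell`` is the
    optional table of per-cell scores."""

    sample_id: str
    per_type: pd.DataFrame
    per_cell: pd.DataFrame | None = None


def same_cell_density(
    cellmap: CellMap,
    k_density: int = 5,
    *,
    keep_cell_scores: bool = False,
) -> DensityResult:
    """Same-cell density score per cell type.

    For each cell of type t (provided the type has more than ``k_density``
    cells), the mean distance to its ``k_density`` nearest same-type
    neighbours (self excluded) is divided by ``sqrt(area / N_t)``.  The
    per-type score is the mean over that type's cells.  Types with too few
    cells are reported with a missing score, never zero.
    """
    if k_density < 1:
        raise ConfigError("k_density must be >= 1")
    if not cellmap.area > 0:
        raise ConfigError("section area must be > 0")
    coords = cellmap.coords
    types = cellmap.cell_types
    rows, cell_rows = [], []
    for t in sorted(set(types)):
        idx = np.flatnonzero(types == t)
        n_t = len(idx)
        if n_t <= k_density:
            rows.append({"sample_id": cellmap.sample_id, "cell_type": t,
                         "mean_score": np.nan, "n_cells": n_t, "tested": False})
            continue
        nb = knn_neighbors(coords[idx], k_density)
        d = np.sqrt(((coords[idx][:, None, :] - coords[idx][nb]) ** 2).sum(axis=2))
        d_mean = d.mean(axis=1)
        d_max = np.sqrt(cellmap.area / n_t)
        scores = d_mean / d_max
        rows.append({"sample_id": cellmap.sample_id, "cell_type": t,
                     "mean_score": float(scores.mean()), "n_cells": n_t,
                     "tested": True})
        if keep_cell_scores:
            ids = cellmap.cells["cell_id"].to_numpy(dtype=object)[idx]
            cell_rows.extend(
                {"cell_id": cid, "cell_type": t, "score": float(s)}
                for cid, s in zip(ids, scores))
    per_type = pd.DataFrame(rows)
    per_cell = pd.DataFrame(cell_rows) if keep_cell_scores else None
    return DensityResult(sample_id=cellmap.sample_id, per_type=per_type,
                         per_cell=per_cell)


def correlate_with_covariate(
    values: Iterable[float], covariate: Iterable[float]
) -> tuple[float, float, int]:
    """Pearson correlation between paired per-donor values and a covariate.

    Returns ``(r, two-sided p, n)``; r is NaN (flagged undefined) when either
    vector has zero variance.
    """
    x = np.asarray(list(values), dtype=float)
    y = np.asarray(list(covariate), dtype=float)
    if len(x) != len(y):
        raise ConfigError("values and covariate must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ConfigError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
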