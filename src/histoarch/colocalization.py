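"""Colocalization quotients and colocalization-guided ligand-receptor
nomination.

The colocalization quotient of an ordered type pair A -> B is

    CLQ_{A->B} = (C_{A->B} / N_A) / (N_B / (N - 1))

where C_{A->B} sums, over cells of type A, the fraction of type-B cells
among the cell's k nearest neighbours (self excluded; k default 10), N is
the total cell count and N_A, N_B the type counts.  For the self pair the
denominator uses (N_A - 1) / (N - 1).  CLQ = 1 under random mixing, > 1 when
B is over-represented near A.

Ligand-receptor nomination tests, for every colocalized type pair and every
ligand-receptor gene pair, whether the ligand (in the first type) and the
receptor (in the second type) are both differentially expressed between the
two anatomical groups (two-sided Wilcoxon rank-sum, BH-adjusted within each
(cell type, gene role) family) with higher colon means.  A held-out
validation matrix scores predictions by one-sided Wilcoxon (CL > SB) on both
members, and the prediction success count is compared with a gene-label
permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._knn import knn_neighbors
from .core import CellMap
from .exceptions import ConfigError

__all__ = [
    "CLQMatrix", "clq", "clq_permutation_z", "clq_group_test",
    "lr_differential", "success_rate_permutation", "PermutationTestResult",
]


@dataclass
class CLQMatrix:
    """Ordered-pair CLQ matrix for one sample plus its ingredients."""

    sample_id: str
    matrix: pd.DataFrame    # rows = A (focal), cols = B (neighbour)
    c_matrix: pd.DataFrame  # C_{A->B}
    type_counts: pd.Series
    n: int
    k: int


def clq(cellmap: CellMap, k_clq: int = 10) -> CLQMatrix:
    """Colocalization quotient between all ordered cell-type pairs."""
    n = cellmap.n
    if k_clq >= n:
        raise ConfigError(f"k_clq={k_clq} must be < n={n}")
    types = cellmap.cell_types
    cats = sorted(set(types))
    code_of = {c: i for i, c in enumerate(cats)}
    codes = np.array([code_of[t] for t in types], dtype=np.intp)
    counts = np.bincount(codes, minlength=len(cats)).astype(float)

    nb = knn_neighbors(cellmap.coords, k_clq)
    nb_codes = codes[nb]
    # M[a, b] = total number of b cells among neighbours of a cells
    M = np.zeros((len(cats), len(cats)))
    np.add.at(M, (np.repeat(codes, k_clq), nb_codes.ravel()), 1.0)
    C = M / k_clq

    denom = np.tile(counts / (n - 1), (len(cats), 1))
    np.fill_diagonal(denom, (counts - 1) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        clq_mat = (C / counts[:, None]) / denom
    clq_mat[denom <= 0] = np.nan

    matrix = pd.DataFrame(clq_mat, index=cats, columns=cats)
    c_df = pd.DataFrame(C, index=cats, columns=cats)
    return CLQMatrix(sample_id=cellmap.sample_id, matrix=matrix, c_matrix=c_df,
                     type_counts=pd.Series(counts.astype(int), index=cats),
                     n=n, k=k_clq)


def clq_permutation_z(
    cellmap: CellMap, k_clq: int = 10, n_permutations: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Z-scores of observed CLQs against a cell-type label permutation null
    (positions fixed, labels shuffled).  Used for calibration checks."""
    obs = clq(cellmap, k_clq)
    rng = np.random.default_rng(seed)
    cats = list(obs.matrix.index)
    draws = np.empty((n_permutations, len(cats), len(cats)))
    shuffled = cellmap.cells.copy()
    for i in range(n_permutations):
        shuffled["cell_type"] = rng.permutation(cellmap.cell_types)
        cm = CellMap(cells=shuffled, area=cellmap.area)
        draws[i] = clq(cm, k_clq).matrix.reindex(index=cats, columns=cats).to_numpy()
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs.matrix.to_numpy() - mean) / sd
    return pd.DataFrame(z, index=cats, columns=cats)


def clq_group_test(
    clqs: Sequence[CLQMatrix],
    groups: Mapping[str, str],
    *,
    group_names: tuple[str, str] = ("SB", "CL"),
    min_count: int = 1,
) -> pd.DataFrame:
    """Welch two-sided t-test of each ordered pair's CLQ between groups.

    ``groups`` maps sample_id -> group.  BH adjustment runs across all
    tested pairs; pairs lacking two finite values in either group are
    flagged untested.  ``min_count`` drops samples where either type has
    fewer cells.
    """
    g1, g2 = group_names
    long = []
    for cm in clqs:
        g = groups[cm.sample_id]
        for a in cm.matrix.index:
            for b in cm.matrix.columns:
                if cm.type_counts[a] < min_count or cm.type_counts[b] < min_count:
                    continue
                v = cm.matrix.at[a, b]
                if np.isfinite(v):
                    long.append({"pair_a": a, "pair_b": b, "group": g,
                                 "value": float(v)})
    long = pd.DataFrame(long)
    rows = []
    for (a, b), sub in long.groupby(["pair_a", "pair_b"], sort=True):
        va = sub.loc[sub["group"] == g1, "value"].to_numpy()
        vb = sub.loc[sub["group"] == g2, "value"].to_numpy()
        row = {"pair_a": a, "pair_b": b,
               f"mean_{g1}": va.mean() if len(va) else np.nan,
               f"mean_{g2}": vb.mean() if len(vb) else np.nan,
               f"n_{g1}": len(va), f"n_{g2}": len(vb)}
        if len(va) < 2 or len(vb) < 2:
            row.update(t=np.nan, p=np.nan, tested=False, direction="")
        else:
            if np.ptp(va) == 0 and np.ptp(vb) == 0 and va.mean() == vb.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=False)
            direction = f"{g2}>{g1}" if vb.mean() > va.mean() else f"{g1}>{g2}"
            row.update(t=float(t), p=float(p), tested=True, direction=direction)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = out["tested"] & out["p"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def _rank_sum_p(
    x_hi: np.ndarray, x_lo: np.ndarray, alternative: str
) -> np.ndarray:
    """Vectorized Wilcoxon rank-sum (Mann-Whitney) p-values per column, using
    the normal approximation with tie correction."""
    res = stats.mannwhitneyu(x_hi, x_lo, axis=0, alternative=alternative,
                             method="asymptotic")
    return np.atleast_1d(res.pvalue)


def lr_differential(
    expr: ad.AnnData,
    pairs: pd.DataFrame,
    cell_pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    *,
    groups: tuple[str, str] = ("SB", "CL"),
    min_cells: int = 3,
) -> pd.DataFrame:
    """Nominate ligand-receptor pairs on colocalized cell-type pairs.

    For each colocalized (type_L, type_R) and each (ligand, receptor) gene
    pair, a two-sided Wilcoxon rank-sum compares the ligand in type_L and
    the receptor in type_R between the groups.  P-values are BH-adjusted
    within each (cell type, gene role) family.  A pair is nominated when
    both adjusted p < alpha and both means are higher in the second group
    (colon).  Returns the full test table with a ``nominated`` flag.
    """
    g_lo, g_hi = groups
    genes = list(expr.var_names)
    gene_idx = {g: i for i, g in enumerate(genes)}
    pairs = pairs.drop_duplicates(subset=["ligand", "receptor"])
    missing = sorted((set(pairs["ligand"]) | set(pairs["receptor"])) - set(genes))
    if missing:
        warnings.warn(f"genes absent from the expression matrix: {missing}")
        pairs = pairs[pairs["ligand"].isin(gene_idx)
                      & pairs["receptor"].isin(gene_idx)]

    X = np.asarray(expr.X)
    obs = expr.obs
    # per (type, role): test each needed gene once
    tests: dict[tuple[str, str, str], dict] = {}
    needed: dict[tuple[str, str], set] = {}
    for tl, tr in cell_pairs:
        needed.setdefault((tl, "ligand"), set()).update(pairs["ligand"])
        needed.setdefault((tr, "receptor"), set()).update(pairs["receptor"])
    skipped_types = set()
    for (ct, role), gene_set in sorted(needed.items()):
        hi = (obs["cell_type"] == ct) & (obs["group"] == g_hi)
        lo = (obs["cell_type"] == ct) & (obs["group"] == g_lo)
        if hi.sum() < min_cells or lo.sum() < min_cells:
            skipped_types.add(ct)
            continue
        gl = sorted(gene_set)
        cols = [gene_idx[g] for g in gl]
        x_hi = X[hi.to_numpy()][:, cols]
        x_lo = X[lo.to_numpy()][:, cols]
        p = _rank_sum_p(x_hi, x_lo, "two-sided")
        p_adj = multipletests(p, method="fdr_bh")[1]
        mu_hi, mu_lo = x_hi.mean(axis=0), x_lo.mean(axis=0)
        for g, pv, pa, mh, ml in zip(gl, p, p_adj, mu_hi, mu_lo):
            lfc = np.log2((mh + 1e-9) / (ml + 1e-9))
            tests[(ct, role, g)] = {"p": pv, "p_adj": pa, "log2fc": lfc,
                                    "mean_hi": mh, "mean_lo": ml}
    if skipped_types:
        warnings.warn(f"cell types with <{min_cells} cells per group skipped: "
                      f"{sorted(skipped_types)}")

    rows = []
    for tl, tr in cell_pairs:
        for _, pr in pairs.iterrows():
            lt = tests.get((tl, "ligand", pr["ligand"]))
            rt = tests.get((tr, "receptor", pr["receptor"]))
            if lt is None or rt is None:
                continue
            nominated = (lt["p_adj"] < alpha and rt["p_adj"] < alpha
                         and lt["log2fc"] > 0 and rt["log2fc"] > 0)
            rows.append({
                "cell_type_L": tl, "cell_type_R": tr,
                "ligand": pr["ligand"], "receptor": pr["receptor"],
                "ligand_log2fc": float(lt["log2fc"]),
                "receptor_log2fc": float(rt["log2fc"]),
                "ligand_p_adj": float(lt["p_adj"]),
                "receptor_p_adj": float(rt["p_adj"]),
                "direction": f"{g_hi}>{g_lo}",
                "nominated": bool(nominated),
            })
    return pd.DataFrame(rows)


@dataclass
class PermutationTestResult:
    """Observed prediction success against a gene-label permutation null."""

    observed_successes: int
    n_predictions: int
    n_dropped: int
    success_rate: float
    null_successes: np.ndarray
    p_value: float
    p_value_randomized: float


def success_rate_permutation(
    validation_expr: ad.AnnData,
    predictions: pd.DataFrame,
    n_permutations: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
    *,
    groups: tuple[str, str] = ("SB", "CL"),
) -> PermutationTestResult:
    """Gene-label permutation test of the validation success rate.

    A prediction succeeds when, in the validation matrix, a one-sided
    Wilcoxon (second group > first) is BH-significant for both the ligand in
    its cell type and the receptor in its cell type (BH across all tests of
    the run).  The null permutes the gene labels of the validation matrix
    (columns only, so per-cell count distributions are preserved exactly)
    and recomputes the success count; p = (1 + #{null >= obs}) / (n + 1).

    ``p_value_randomized`` additionally reports the tie-randomized version
    of the empirical p-value (uniform under the null even though the success
    count is integer-valued); the deterministic p above is the primary
    statistic.
    """
    g_lo, g_hi = groups
    genes = list(validation_expr.var_names)
    gene_idx = {g: i for i, g in enumerate(genes)}
    obs_df = validation_expr.obs
    types_avail = set(obs_df["cell_type"])

    keep = predictions[
        predictions["cell_type_L"].isin(types_avail)
        & predictions["cell_type_R"].isin(types_avail)
        & predictions["ligand"].isin(gene_idx)
        & predictions["receptor"].isin(gene_idx)
    ].reset_index(drop=True)
    n_dropped = len(predictions) - len(keep)
    if len(keep) == 0:
        raise ConfigError("no predictions match the validation matrix")

    X = np.asarray(validation_expr.X)
    types_needed = sorted(set(keep["cell_type_L"]) | set(keep["cell_type_R"]))
    # one-sided p for every (type, gene): permuting gene labels only permutes
    # which column a prediction reads, so this matrix covers every null draw
    p_lookup = {}
    for ct in types_needed:
        hi = (obs_df["cell_type"] == ct) & (obs_df["group"] == g_hi)
        lo = (obs_df["cell_type"] == ct) & (obs_df["group"] == g_lo)
        if hi.sum() < 1 or lo.sum() < 1:
            raise ConfigError(f"validation matrix lacks {ct!r} cells in a group")
        p_lookup[ct] = _rank_sum_p(X[hi.to_numpy()], X[lo.to_numpy()], "greater")

    tl = keep["cell_type_L"].to_numpy(dtype=object)
    tr = keep["cell_type_R"].to_numpy(dtype=object)
    lig = np.array([gene_idx[g] for g in keep["ligand"]], dtype=np.intp)
    rec = np.array([gene_idx[g] for g in keep["receptor"]], dtype=np.intp)
    p_l_rows = np.vstack([p_lookup[t] for t in tl])   # (m, n_genes)
    p_r_rows = np.vstack([p_lookup[t] for t in tr])
    m = len(keep)

    def successes(perm: np.ndarray) -> int:
        pl = p_l_rows[np.arange(m), perm[lig]]
        pr = p_r_rows[np.arange(m), perm[rec]]
        p_all = np.concatenate([pl, pr])
        adj = multipletests(p_all, method="fdr_bh")[1]
        return int(((adj[:m] < alpha) & (adj[m:] < alpha)).sum())

    identity = np.arange(len(genes))
    observed = successes(identity)

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        null[i] = successes(rng.permutation(len(genes)))

    ge = int((null >= observed).sum())
    p = (1 + ge) / (n_permutations + 1)
    gt = int((null > observed).sum())
    ties = ge - gt
    u = rng.random()
    p_rand = (gt + u * (1 + ties)) / (n_permutations + 1)
    return PermutationTestResult(
        observed_successes=observed, n_predictions=m, n_dropped=n_dropped,
        success_rate=observed / m, null_successes=null,
        p_value=float(p), p_value_randomized=float(p_rand))
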