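"""End-to-end orchestration of the multiscale architecture analysis.

``run_pipeline`` takes a cohort of CellMaps and an :class:`AnalysisConfig`
and produces every stage's artifact: density scores, composition tables and
group tests, neighbourhood / community / tissue-unit labels (clustered
jointly across samples), enrichment matrices and SB-vs-CL conservation
deltas, the hierarchy graph, spatial-context combinations with their
containment graph, per-group motif tests, and per-sample CLQ matrices with
the cross-group CLQ test.  All stages derive their seeds from the config
seed, so outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import pandas as pd

from .colocalization import CLQMatrix, clq, clq_group_test
from .composition import compare_groups, compartment_percentages, same_cell_density
from .config import AnalysisConfig
from .context import combination_graph, context_combinations
from .core import CellMap, LabelAssignment, concat_labels
from .exceptions import ConfigError
from .hierarchy import build_hierarchy_graph
from .motifs import label_instances, motif_test, union_graphs
from .neighborhoods import (
    WindowMatrix, cluster_windows, composition_windows, enrichment_matrix,
)

__all__ = ["PipelineResult", "run_pipeline", "cohort_windows", "cohort_level"]


def cohort_windows(
    cellmaps: Sequence[CellMap],
    labels: Sequence[LabelAssignment] | None,
    k: int,
    *,
    include_self: bool = True,
) -> WindowMatrix:
    """Window matrices computed per sample (windows never cross sample
    boundaries) and stacked over the union of label columns."""
    per_map = []
    for i, cm in enumerate(cellmaps):
        la = labels[i] if labels is not None else None
        per_map.append(composition_windows(cm, la, k, include_self=include_self))
    cols = sorted(set().union(*(w.values.columns for w in per_map)))
    stacked = pd.concat(
        [w.values.reindex(columns=cols, fill_value=0.0) for w in per_map])
    return WindowMatrix(values=stacked, k=k, level=per_map[0].level,
                        include_self=include_self)


def _split(stacked: LabelAssignment, cellmaps: Sequence[CellMap]) -> list[LabelAssignment]:
    out, start = [], 0
    for cm in cellmaps:
        out.append(LabelAssignment(level=stacked.level,
                                   labels=stacked.labels[start:start + cm.n],
                                   meta=stacked.meta))
        start += cm.n
    return out


def cohort_level(
    cellmaps: Sequence[CellMap],
    lower: Sequence[LabelAssignment] | None,
    k: int,
    n_clusters: int,
    seed: int,
    level: str,
) -> list[LabelAssignment]:
    """One structural level clustered jointly across the cohort."""
    windows = cohort_windows(cellmaps, lower, k)
    stacked = cluster_windows(windows, n_clusters, seed, level=level,
                              prefix=level[0].upper())
    return _split(stacked, cellmaps)


@dataclass
class PipelineResult:
    config: AnalysisConfig
    density: pd.DataFrame
    composition: pd.DataFrame
    composition_test: pd.DataFrame
    labels: dict[str, list[LabelAssignment]]
    enrichment: pd.DataFrame
    conservation: pd.DataFrame | None
    hierarchy: nx.DiGraph
    context_table: pd.DataFrame
    context_graph: nx.DiGraph
    motif_tables: dict[str, pd.DataFrame]
    clq_matrices: list[CLQMatrix]
    clq_test: pd.DataFrame | None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    graphs: dict[str, nx.Graph] = field(default_factory=dict)


def run_pipeline(
    cellmaps: Sequence[CellMap], config: AnalysisConfig | None = None
) -> PipelineResult:
    if config is None:
        config = AnalysisConfig()
    if not cellmaps:
        raise ConfigError("no cell maps supplied")
    cellmaps = sorted(cellmaps, key=lambda cm: cm.sample_id)
    seed = config.seed

    # --- density and composition ---------------------------------------
    density = pd.concat(
        [same_cell_density(cm, config.k_density).per_type for cm in cellmaps],
        ignore_index=True)
    composition = compartment_percentages(cellmaps)
    donor_vals = (composition[composition["category"] == "all"]
                  .groupby(["donor_id", "group", "cell_type"], sort=True)
                  ["percentage"].mean().reset_index())
    groups_present = sorted(set(donor_vals["group"]))
    if set(groups_present) >= {"SB", "CL"}:
        composition_test = compare_groups(donor_vals)
    else:
        composition_test = pd.DataFrame()

    # --- structural levels ---------------------------------------------
    type_labels = [cm.type_labels() for cm in cellmaps]
    nbhd = cohort_level(cellmaps, None, config.k_window_nbhd,
                        config.n_clusters_nbhd, seed, "neighbourhood")
    comm = cohort_level(cellmaps, nbhd, config.k_window_comm,
                        config.n_clusters_comm, seed + 1, "community")
    tissue = cohort_level(cellmaps, comm, config.k_window_tissue,
                          config.n_clusters_comm, seed + 2, "tissue_unit")
    labels = {"cell_type": type_labels, "neighbourhood": nbhd,
              "community": comm, "tissue_unit": tissue}

    # --- enrichment + conservation --------------------------------------
    all_types = concat_labels(type_labels)
    all_nbhd = concat_labels(nbhd)
    enr = enrichment_matrix(all_nbhd, all_types)
    enrichment = enr.matrix.reset_index(names="label")

    conservation = None
    group_of = {cm.sample_id: cm.group for cm in cellmaps}
    if set(group_of.values()) >= {"SB", "CL"}:
        def group_enrich(g: str):
            idx = [i for i, cm in enumerate(cellmaps) if cm.group == g]
            u = concat_labels([nbhd[i] for i in idx])
            l = concat_labels([type_labels[i] for i in idx])
            return enrichment_matrix(u, l)
        from .neighborhoods import conservation_delta
        delta = conservation_delta(group_enrich("SB"), group_enrich("CL"))
        conservation = delta.delta.reset_index(names="label")

    # --- hierarchy -------------------------------------------------------
    hier = build_hierarchy_graph(
        [all_types, all_nbhd, concat_labels(comm), concat_labels(tissue)],
        threshold=config.hierarchy_threshold)

    # --- spatial context (neighbourhood level, k_window_comm windows) ----
    ctx_tables = []
    per_cell_total = 0
    for cm, la in zip(cellmaps, nbhd):
        k_ctx = min(config.k_window_comm, cm.n)
        res = context_combinations(cm, la, k_ctx, config.context_threshold)
        ctx_tables.append(res.table)
        per_cell_total += res.n_cells
    merged = (pd.concat(ctx_tables)
              .groupby("combination", sort=True)
              .agg(size=("size", "first"), count=("count", "sum"))
              .reset_index())
    merged["frequency"] = merged["count"] / per_cell_total
    merged = merged.sort_values(["count", "combination"],
                                ascending=[False, True]).reset_index(drop=True)
    from .context import ContextResult
    ctx_res = ContextResult(table=merged, per_cell=[], n_cells=per_cell_total,
                            threshold=config.context_threshold,
                            k=config.k_window_comm)
    ctx_graph = combination_graph(ctx_res, config.context_min_freq)
    context_table = merged.assign(
        combination=merged["combination"].map(lambda c: "+".join(c)))

    # --- motifs per group (community instances) --------------------------
    motif_tables: dict[str, pd.DataFrame] = {}
    for g in sorted(set(group_of.values())):
        graphs = [label_instances(cm, comm[i])
                  for i, cm in enumerate(cellmaps) if cm.group == g]
        if not graphs:
            continue
        union = union_graphs(graphs)
        motif_tables[g] = motif_test(union, config.n_permutations, seed + 10,
                                     config.motif_min_instances)

    # --- CLQ --------------------------------------------------------------
    clq_mats = [clq(cm, config.k_clq) for cm in cellmaps]
    clq_test = None
    if set(group_of.values()) >= {"SB", "CL"}:
        clq_test = clq_group_test(clq_mats, group_of)

    # --- collected writable artifacts ------------------------------------
    tables: dict[str, pd.DataFrame] = {
        "density": density,
        "composition": composition,
        "enrichment_neighbourhood": enrichment,
        "context_combinations": context_table,
    }
    if len(composition_test):
        tables["composition_test"] = composition_test
    if conservation is not None:
        tables["conservation_delta"] = conservation
    for g, t in motif_tables.items():
        tables[f"motifs_{g}"] = t
    clq_long = pd.concat(
        [m.matrix.rename_axis(index="pair_a", columns="pair_b").stack()
         .rename("clq").reset_index().assign(sample_id=m.sample_id)
         for m in clq_mats], ignore_index=True)
    tables["clq"] = clq_long[["sample_id", "pair_a", "pair_b", "clq"]]
    if clq_test is not None:
        tables["clq_test"] = clq_test
    label_table = pd.concat([
        pd.DataFrame({
            "cell_id": cm.cells["cell_id"],
            "sample_id": cm.sample_id,
            "neighbourhood": nbhd[i].labels,
            "community": comm[i].labels,
            "tissue_unit": tissue[i].labels,
        }) for i, cm in enumerate(cellmaps)], ignore_index=True)
    tables["labels"] = label_table
    graphs: dict[str, nx.Graph] = {"hierarchy": hier, "context_graph": ctx_graph}

    return PipelineResult(
        config=config, density=density, composition=composition,
        composition_test=composition_test, labels=labels,
        enrichment=enrichment, conservation=conservation, hierarchy=hier,
        context_table=context_table, context_graph=ctx_graph,
        motif_tables=motif_tables, clq_matrices=clq_mats, clq_test=clq_test,
        tables=tables, graphs=graphs)
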