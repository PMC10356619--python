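"""Readers and writers for cell tables, result tables and graphs.

Cell tables are CSV/TSV with columns ``cell_id, x, y, cell_type, sample_id``
plus optional ``donor_id, region, group, compartment``; one CellMap is
produced per distinct sample_id, with section area computed from the convex
hull of the coordinates unless overridden.  Result tables are written as TSV
with a fixed column order, ``NA`` for missing values and 6-significant-digit
floats so repeated runs are byte-identical; graphs are written as GraphML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .config import AnalysisConfig
from .core import CELL_COLUMNS, OPTIONAL_COLUMNS, CellMap
from .exceptions import HistoarchError, IntegrityError, SchemaError

__all__ = [
    "read_cell_table", "write_cell_table", "write_results",
    "read_category_map", "read_merge_mapping", "read_lr_pairs",
    "read_expression", "write_expression",
]

log = logging.getLogger("histoarch")


def _hull_area(xy: np.ndarray) -> float:
    """Convex-hull area of the cell coordinates (2-D hull "volume")."""
    try:
        return float(ConvexHull(xy).volume)
    except (QhullError, ValueError) as exc:
        raise IntegrityError(
            "cannot compute a convex-hull area (fewer than 3 distinct "
            "non-collinear cells); pass area_override") from exc


def read_cell_table(
    path: str | Path,
    area_override: float | Mapping[str, float] | None = None,
) -> dict[str, CellMap]:
    """Read a cell table into one CellMap per sample_id (sorted by id).

    Missing optional columns are filled with ``"unknown"``; the section area
    is the convex hull of each sample's coordinates unless ``area_override``
    (a scalar, or a mapping sample_id -> area) is given.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory column(s) {missing}")
    for col in ("x", "y"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise SchemaError(f"{path.name}: non-numeric {col} at line {row}")
        df[col] = num
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown"
        else:
            df[col] = df[col].fillna("unknown")

    out: dict[str, CellMap] = {}
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.sort_values("cell_id").reset_index(drop=True)
        if sub["cell_id"].duplicated().any():
            dup = sub.loc[sub["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise IntegrityError(
                f"{path.name}: duplicate cell_id {dup!r} in sample {sid!r}")
        if area_override is None:
            area = _hull_area(sub[["x", "y"]].to_numpy(dtype=float))
        elif isinstance(area_override, Mapping):
            area = float(area_override[sid])
        else:
            area = float(area_override)
        out[str(sid)] = CellMap(cells=sub, area=area)
    log.info("read %d cells in %d sample(s) from %s",
             len(df), len(out), path.name)
    return out


_FLOAT_FMT = "%.6g"


def _format_table(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format=_FLOAT_FMT,
                     na_rep="NA", lineterminator="\n")


def write_cell_table(cellmaps: Sequence[CellMap], path: str | Path) -> None:
    """Write CellMaps back to one TSV/CSV cell table (round-trippable)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.concat([cm.cells for cm in cellmaps], ignore_index=True)
    cols = list(CELL_COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep=sep, index=False, na_rep="NA",
                    lineterminator="\n")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    graphs: Mapping[str, nx.Graph],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    *,
    force: bool = False,
) -> dict:
    """Write named tables (TSV) and graphs (GraphML) plus a manifest.

    Output is deterministic: fixed column order as given, 6-significant-digit
    floats, ``NA`` for missing values, sorted manifest keys.  Existing files
    raise unless ``force`` is set.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = list(tables) + list(graphs)
    if len(set(names)) != len(names):
        raise HistoarchError("table/graph name collision in write_results")
    entries = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        if p.exists() and not force:
            raise HistoarchError(f"refusing to overwrite {p}; pass force=True")
        p.write_text(_format_table(df))
        entries.append({"name": p.name, "rows": int(len(df))})
    for name, g in graphs.items():
        p = out_dir / f"{name}.graphml"
        if p.exists() and not force:
            raise HistoarchError(f"refusing to overwrite {p}; pass force=True")
        nx.write_graphml(g, p)
        entries.append({"name": p.name,
                        "nodes": g.number_of_nodes(),
                        "edges": g.number_of_edges()})
    manifest = {
        "files": sorted(entries, key=lambda e: e["name"]),
        "config_hash": config.hash() if config is not None else None,
    }
    mp = out_dir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %d artifact(s) to %s", len(entries), out_dir)
    return manifest


def read_category_map(path: str | Path) -> dict[str, str]:
    """CSV with columns cell_type,category -> mapping."""
    df = pd.read_csv(path)
    for col in ("cell_type", "category"):
        if col not in df.columns:
            raise SchemaError(f"category map missing column {col!r}")
    return dict(zip(df["cell_type"].astype(str), df["category"].astype(str)))


def read_merge_mapping(path: str | Path) -> dict[str, str]:
    """CSV with columns old_label,new_label -> cluster merge mapping."""
    df = pd.read_csv(path)
    for col in ("old_label", "new_label"):
        if col not in df.columns:
            raise SchemaError(f"merge mapping missing column {col!r}")
    return dict(zip(df["old_label"].astype(str), df["new_label"].astype(str)))


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    """FANTOM5-style ligand-receptor pair CSV (ligand,receptor[,source])."""
    df = pd.read_csv(path)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise SchemaError(f"ligand-receptor table missing column {col!r}")
    if "source" not in df.columns:
        df["source"] = "user"
    df = df.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)
    if (df["ligand"].astype(str) == "").any() or (df["receptor"].astype(str) == "").any():
        raise SchemaError("empty gene name in ligand-receptor table")
    return df


def read_expression(path: str | Path):
    """Dense expression CSV (cell_id, cell_type, group, sample_id, genes...)
    into an AnnData."""
    import anndata as ad

    df = pd.read_csv(path)
    meta_cols = ["cell_id", "cell_type", "group", "sample_id"]
    for col in meta_cols:
        if col not in df.columns:
            raise SchemaError(f"expression table missing column {col!r}")
    genes = [c for c in df.columns if c not in meta_cols]
    X = df[genes].to_numpy(dtype=np.int64)
    obs = df[meta_cols[1:]].copy()
    obs.index = df["cell_id"].astype(str)
    adata = ad.AnnData(X=X, obs=obs)
    adata.var_names = genes
    return adata


def write_expression(adata, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(adata.X), columns=list(adata.var_names))
    df.insert(0, "sample_id", adata.obs["sample_id"].to_numpy())
    df.insert(0, "group", adata.obs["group"].to_numpy())
    df.insert(0, "cell_type", adata.obs["cell_type"].to_numpy())
    df.insert(0, "cell_id", adata.obs_names)
    df.to_csv(path, index=False, lineterminator="\n")
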