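"""Readers and writers for the plain-text formats the pipeline consumes.

ASV tables travel as TSV (samples as rows, ASVs as columns, or transposed)
or BIOM v1 (JSON); sample metadata and taxonomy as TSV; distance matrices as
square TSV; networks as GraphML or weighted edge-list CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .asv import AsvTable
from .bioenergetics import CompositionProfile, TankGrowthRecord

__all__ = [
    "read_asv_table",
    "write_asv_table",
    "read_biom_json",
    "read_metadata",
    "read_taxonomy",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_graphml",
    "write_edge_list",
    "read_tank_records",
    "read_composition_profiles",
]

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

PathLike = Union[str, Path]


def read_asv_table(
    path: PathLike,
    metadata: Optional[pd.DataFrame] = None,
    orientation: str = "asvs-as-columns",
) -> AsvTable:
    """Read a TSV count table.

    ``orientation="asvs-as-columns"`` expects samples as rows;
    ``"asvs-as-rows"`` transposes (the common QIIME-style export).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if orientation == "asvs-as-rows":
        df = df.T
    elif orientation != "asvs-as-columns":
        raise ValueError(f"unknown orientation {orientation!r}")
    return AsvTable(df, metadata)


def write_asv_table(table: AsvTable, path: PathLike) -> None:
    table.counts.to_csv(path, sep="\t")


def read_biom_json(path: PathLike, metadata: Optional[pd.DataFrame] = None) -> AsvTable:
    """Read a BIOM v1 (JSON) table.

    Supports both sparse and dense matrix_type; BIOM stores observations
    (ASVs) as rows, which is transposed into the samples-x-ASVs layout.
    """
    with open(path) as fh:
        doc = json.load(fh)
    obs_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"])
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=obs_ids)
    return AsvTable(counts, metadata)


def read_metadata(path: PathLike) -> pd.DataFrame:
    """Sample metadata TSV, first column = sample id."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def read_taxonomy(path: PathLike) -> pd.DataFrame:
    """Taxonomy TSV: either 7 rank columns, or one semicolon-delimited column.

    Returns a DataFrame indexed by ASV id with the 7 canonical rank columns;
    missing assignments are left empty (downstream code fills
    ``unclassified_<rank>`` placeholders).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 1:
        col = df.columns[0]
        split = df[col].fillna("").str.split(";", expand=True)
        split = split.iloc[:, : len(RANKS)]
        split.columns = RANKS[: split.shape[1]]
        for r in RANKS[split.shape[1]:]:
            split[r] = ""
        df = split
    else:
        df = df.rename(columns={c: c.lower() for c in df.columns})
        missing = [r for r in RANKS if r not in df.columns]
        for r in missing:
            df[r] = ""
    return df[RANKS].apply(lambda s: s.str.strip().fillna(""))


def read_distance_matrix(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("distance matrix must be square")
    return df


def write_distance_matrix(dm, path: PathLike) -> None:
    """Write a skbio DistanceMatrix or square DataFrame as TSV."""
    if hasattr(dm, "to_data_frame"):
        dm = dm.to_data_frame()
    dm.to_csv(path, sep="\t")


def write_graphml(graph: nx.Graph, path: PathLike) -> None:
    nx.write_graphml(graph, str(path))


def write_edge_list(graph: nx.Graph, path: PathLike) -> None:
    """Weighted edge list CSV: source, target, r, p_adj, sign."""
    rows = [
        {
            "source": u,
            "target": v,
            "r": d.get("r"),
            "p_adj": d.get("p_adj"),
            "sign": d.get("sign"),
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p_adj", "sign"]).to_csv(
        path, index=False
    )


# -- bioenergetics tabular input -----------------------------------------

TANK_COLUMNS = {
    "n_initial": int,
    "n_final": int,
    "w_initial": float,
    "w_final": float,
    "duration": float,
    "feed_intake": float,
}


def read_tank_records(path: PathLike) -> dict[str, TankGrowthRecord]:
    """Tidy TSV of tank growth records, one row per tank.

    Required columns: tank, n_initial, n_final, w_initial, w_final,
    duration, feed_intake.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"tank", *TANK_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"tank records missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        kwargs = {c: conv(row[c]) for c, conv in TANK_COLUMNS.items()}
        out[str(row["tank"])] = TankGrowthRecord(**kwargs)
    return out


def read_composition_profiles(path: PathLike) -> dict[str, CompositionProfile]:
    """Tidy TSV of composition profiles, one row per sample.

    Required columns: sample, role; any subset of the CompositionProfile
    nutrient fields as further columns (blank = not measured).
    """
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "role" not in df.columns:
        raise ValueError("composition table needs 'sample' and 'role' columns")
    fields = [
        "dry_matter", "crude_protein", "crude_fat", "ash", "carbohydrate",
        "gross_energy", "yttrium", "phosphorus", "calcium", "magnesium",
        "nitrogen",
    ]
    out = {}
    for _, row in df.iterrows():
        kwargs = {}
        for f in fields:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = float(row[f])
        out[str(row["sample"])] = CompositionProfile(role=str(row["role"]), **kwargs)
    return out
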