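"""Readers and writers for every external format the pipeline touches.

Formats are deliberately plain: tab-separated expression matrix and
design tables, GMT gene-set collections, two-column edge lists, and
TSV result tables. Every reader validates and reports the offending
row/column on failure.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DESIGN_COLUMNS, ExpressionDataset, GeneSetCollection, InteractionGraph

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "write_table",
    "read_table",
]


def read_expression_matrix(path, design_path) -> ExpressionDataset:
    """Read a gene × sample TSV matrix together with its design table.

    The matrix file has gene ids in the first column and a header row of
    sample ids; the design file has columns ``sample_id``, ``group``,
    ``timepoint_h``, ``replicate``. Design rows are matched to the matrix
    header by sample id; sample order follows the matrix header.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    arr = values.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(arr.isna().to_numpy() & values.notna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-numeric cell at gene {values.index[i]!r}, "
            f"sample {values.columns[j]!r} in {path}"
        )
    design = pd.read_csv(design_path, sep="\t")
    missing = [c for c in ("sample_id", *DESIGN_COLUMNS) if c not in design.columns]
    if missing:
        raise ValueError(f"design file {design_path} missing columns: {missing}")
    design = design.set_index("sample_id")
    absent = [s for s in values.columns if s not in design.index]
    if absent:
        raise ValueError(f"design file lacks samples present in matrix header: {absent}")
    return ExpressionDataset(arr.astype(float), design)


def write_expression_matrix(data: ExpressionDataset, path, design_path) -> None:
    data.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")
    data.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated
    ``name<TAB>description<TAB>member...``. Members are deduplicated
    preserving first occurrence; duplicate set names and empty member
    lists are rejected."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, tuple(dict.fromkeys(members)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.description(name)
            members = collection.members(name)
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_edge_list(path) -> InteractionGraph:
    """Read a two-column TSV of gene pairs as an undirected graph.

    Reversed duplicates collapse to one edge; self-loops are dropped
    (with a logged count); extra columns are ignored. An empty file
    yields an empty graph.
    """
    edges = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(f"{path}: malformed edge at line {lineno}: {line!r}")
            edges.append((fields[0], fields[1]))
    graph = InteractionGraph(edges)
    if graph.n_self_loops_dropped:
        logger.warning(
            "%s: dropped %d self-loop edge(s)", path, graph.n_self_loops_dropped
        )
    return graph


def write_edge_list(graph: InteractionGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV: UTF-8, header row, floats at six
    significant digits, NaN rendered as ``NA``, row order preserved."""
    records.to_csv(
        Path(path), sep="\t", index=False, float_format="%.6g", na_rep="NA"
    )


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
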