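"""Core in-memory containers shared by every pipeline stage.

The pipeline operates on three kinds of objects: a log2 gene-by-sample
expression matrix with its sample design, named gene-set collections
(GO terms / pathways), and an undirected gene–gene interaction graph.
All three validate their invariants on construction so downstream stages
can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "GeneSetCollection", "InteractionGraph"]

#: design table columns required for every sample
DESIGN_COLUMNS = ("group", "timepoint_h", "replicate")


@dataclass
class ExpressionDataset:
    """A gene × sample matrix of log2 intensities plus the sample design.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are genes (index = gene ids), columns are samples
        (columns = sample ids). Values are log2-scale intensities.
    design : pandas.DataFrame
        Indexed by sample id with columns ``group`` (free string label,
        e.g. "CpG" or "PBS"), ``timepoint_h`` (hours, positive) and
        ``replicate`` (positive integer).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        v, d = self.values, self.design
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        missing_cols = [c for c in DESIGN_COLUMNS if c not in d.columns]
        if missing_cols:
            raise ValueError(f"design table missing columns: {missing_cols}")
        if d.index.duplicated().any():
            dup = d.index[d.index.duplicated()][0]
            raise ValueError(f"duplicate sample in design: {dup!r}")
        absent = [s for s in v.columns if s not in d.index]
        if absent:
            raise ValueError(f"samples missing from design: {absent}")
        # keep design aligned with the matrix column order
        self.design = d.loc[list(v.columns)]
        arr = v.to_numpy()
        if arr.dtype == object:
            raise ValueError("expression matrix contains non-numeric cells")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (self.design["timepoint_h"] <= 0).any():
            bad = self.design.index[self.design["timepoint_h"] <= 0][0]
            raise ValueError(f"non-positive timepoint for sample {bad!r}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for(self, group: str, timepoint_h: float | None = None) -> list[str]:
        """Sample ids belonging to *group*, optionally at one timepoint."""
        mask = self.design["group"] == group
        if timepoint_h is not None:
            mask &= self.design["timepoint_h"] == timepoint_h
        return list(self.design.index[mask])

    def subset_genes(self, genes) -> "ExpressionDataset":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionDataset(self.values.loc[genes], self.design.copy())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.design.copy())


@dataclass
class GeneSetCollection:
    """Named gene sets (GO terms or pathways) with member gene ids.

    ``sets`` maps set name -> (description, tuple of member gene ids).
    Members are deduplicated preserving first occurrence; empty sets are
    rejected.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, members) in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            deduped = tuple(dict.fromkeys(members))
            if not deduped:
                raise ValueError(f"gene set {name!r} has no members")
            clean[name] = (desc, deduped)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def items(self):
        for name, (_, members) in self.sets.items():
            yield name, members


class InteractionGraph:
    """Undirected gene–gene interaction graph (simple: no self-loops,
    no parallel edges). Thin wrapper over :class:`networkx.Graph` that
    enforces the invariants at construction."""

    def __init__(self, edges=(), nodes=()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        n_self = 0
        for u, v in edges:
            if u == v:
                n_self += 1
                continue
            g.add_edge(u, v)
        self.graph = g
        self.n_self_loops_dropped = n_self

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractionGraph":
        out = cls.__new__(cls)
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from((u, v) for u, v in g.edges if u != v)
        out.graph = h
        out.n_self_loops_dropped = sum(1 for u, v in g.edges if u == v)
        return out

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node):
        return self.graph.degree[node]

    def __contains__(self, node) -> bool:
        return node in self.graph
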