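"""Connectivity-based hub ranking within an interaction graph.

Given an undirected gene–gene interaction graph (a user-supplied
knowledge-base stand-in) and the significantly up-regulated genes of a
treatment, genes are ranked by their degree within the subgraph induced
by the significant genes — the gene with the most interactions with
other significant genes is the "main interactor". Cross-treatment
membership (exclusive to either treatment, or shared) is annotated for
display.
"""

from __future__ import annotations

import logging

import pandas as pd

from .datatypes import InteractionGraph

logger = logging.getLogger(__name__)

__all__ = ["induced_subgraph", "main_interactors", "shared_and_exclusive"]


def induced_subgraph(graph: InteractionGraph, genes) -> InteractionGraph:
    """Subgraph on ``genes ∩ graph nodes``; edges keep both endpoints."""
    keep = set(genes) & set(graph.nodes)
    if not keep:
        logger.warning("no supplied gene appears in the interaction graph")
    sub = graph.graph.subgraph(keep).copy()
    return InteractionGraph.from_networkx(sub)


def main_interactors(
    subgraph: InteractionGraph,
    top_n: int = 10,
    full_graph: InteractionGraph | None = None,
    membership: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank genes of the induced subgraph by degree.

    Descending degree, ties broken lexicographically by gene id; rank 1
    is the main interactor. ``full_graph`` adds the gene's degree in the
    whole graph as a secondary column; ``membership`` (gene -> flag,
    e.g. "A"/"B"/"shared") is carried through. The full ranking is
    returned with a ``top`` flag marking the first ``top_n`` rows.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    rows = []
    for gene in subgraph.nodes:
        row = {"gene": gene, "degree": subgraph.degree(gene)}
        if full_graph is not None:
            row["degree_full_graph"] = (
                full_graph.degree(gene) if gene in full_graph else 0
            )
        if membership is not None:
            row["membership"] = membership.get(gene, "")
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        out["rank"] = pd.Series(dtype=int)
        out["top"] = pd.Series(dtype=bool)
        return out
    out = out.sort_values(["degree", "gene"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    out["top"] = out["rank"] <= top_n
    return out


def shared_and_exclusive(set_a, set_b) -> tuple[list, list, list]:
    """(A-only, B-only, shared), each sorted — the coloring rule of the
    two-treatment network display."""
    a, b = set(set_a), set(set_b)
    return sorted(a - b), sorted(b - a), sorted(a & b)
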