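"""Pathway-clinical bipartite association graph.

Each differentially tested protein gets a volcano-style relative
importance

    R = sqrt( log2FC^2 + (-log10 adjusted p)^2 ),

the Euclidean norm of its volcano-plot coordinates.  For a protein whose
correlation with a clinical variable is significant at raw p < alpha,
the protein-level edge weight is w = rho * R; protein-level weights are
aggregated (sum by default, mean optionally) into a single edge between
the pathway node and the clinical-variable node.  Pathways enter through
their over-representation hit members, so every edge is backed by at
least one significantly correlated, differentially expressed protein.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from .enrichment import EnrichmentRecord

__all__ = ["importance_R", "edge_weight", "build_graph", "graph_edge_table", "P_ADJ_FLOOR"]

# Adjusted p-values are floored before -log10: published values reach
# 1e-28 and a literal zero would give infinite importance.
P_ADJ_FLOOR = 1e-300


def importance_R(log2fc: float, p_adj: float) -> float:
    """Volcano-norm relative importance of one protein.

    Requires p_adj in (0, 1]; callers floor tiny adjusted p at
    ``P_ADJ_FLOOR`` before calling.
    """
    if not 0.0 < p_adj <= 1.0:
        raise ValueError(f"p_adj must be in (0, 1], got {p_adj} (floor tiny values first)")
    if not math.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    return math.hypot(log2fc, -math.log10(p_adj))


def edge_weight(rho: float, R: float) -> float:
    """Protein-level edge weight w = rho * R; the sign carries direction."""
    if R < 0:
        raise ValueError(f"R must be non-negative, got {R}")
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    return rho * R


def build_graph(
    enriched_terms: list[EnrichmentRecord],
    de_table: pd.DataFrame,
    associations: pd.DataFrame,
    alpha: float = 0.05,
    aggregate: str = "sum",
) -> nx.Graph:
    """Assemble the bipartite pathway-clinical graph.

    ``de_table`` is indexed by protein id with ``log2fc`` and ``p_adj``
    columns; ``associations`` is indexed by protein id with ``variable``,
    ``rho`` and raw ``p`` columns (concatenate panels to cover several
    clinical variables).  The significance gate is the *raw* correlation
    p-value at ``alpha``.  One edge per (term, variable) that has at
    least one passing protein; edge attributes are the aggregated signed
    weight and the count of contributing proteins.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"aggregate must be 'sum' or 'mean', got {aggregate!r}")
    needed = {"log2fc", "p_adj"}
    if not needed <= set(de_table.columns):
        raise ValueError(f"de_table needs columns {sorted(needed)}")
    missing = sorted(
        {m for rec in enriched_terms for m in rec.hit_members} - set(de_table.index)
    )
    if missing:
        raise ValueError(f"term members absent from de_table: {missing}")

    g = nx.Graph()
    for rec in enriched_terms:
        g.add_node(rec.term_id, node_type="pathway")
    for var in pd.unique(associations["variable"]):
        g.add_node(str(var), node_type="clinical")

    sig = associations.loc[associations["p"] < alpha]
    for rec in enriched_terms:
        members = set(rec.hit_members)
        for var, panel in sig.groupby("variable", sort=True):
            weights = []
            detail = []
            for pid, row in panel.iterrows():
                if pid not in members:
                    continue
                p_adj = max(float(de_table.loc[pid, "p_adj"]), P_ADJ_FLOOR)
                r_val = importance_R(float(de_table.loc[pid, "log2fc"]), p_adj)
                w = edge_weight(float(row["rho"]), r_val)
                weights.append(w)
                detail.append({"protein_id": pid, "rho": float(row["rho"]), "R": r_val, "w": w})
            if not weights:
                continue
            w_agg = sum(weights) if aggregate == "sum" else sum(weights) / len(weights)
            g.add_edge(rec.term_id, str(var), weight=w_agg, n_proteins=len(weights), proteins=detail)
    return g


def graph_edge_table(graph: nx.Graph) -> pd.DataFrame:
    """Flat edge list (pathway, variable, weight, n_proteins), sorted."""
    rows = []
    for u, v, attrs in graph.edges(data=True):
        if graph.nodes[u]["node_type"] == "pathway":
            pathway, var = u, v
        else:
            pathway, var = v, u
        rows.append(
            {
                "pathway": pathway,
                "variable": var,
                "weight": attrs["weight"],
                "n_proteins": attrs["n_proteins"],
            }
        )
    out = pd.DataFrame(rows, columns=["pathway", "variable", "weight", "n_proteins"])
    return out.sort_values(["pathway", "variable"], kind="mergesort").reset_index(drop=True)
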