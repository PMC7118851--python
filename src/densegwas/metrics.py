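"""Betweenness centrality of merged module networks.

Raw betweenness of a node v is the Freeman sum over unordered pairs
sum_{s != v != t} sigma_st(v) / sigma_st, computed with the Brandes
accumulation algorithm; values are normalized per connected component by
(n - 1)(n - 2) / 2 (n = component size) so a cut vertex on every pair's
unique shortest path scores exactly 1.  High-betweenness genes join
communities of dense subnetworks and are reported as "central".
"""

from __future__ import annotations

from collections.abc import Iterable

import networkx as nx
import pandas as pd

from .errors import ConfigError, DomainError

__all__ = ["betweenness", "classify_central", "attach_betweenness"]


def betweenness(graph: nx.Graph) -> pd.DataFrame:
    """Raw and Freeman-normalized betweenness, per connected component.

    Returns a DataFrame with columns ``gene, raw, normalized`` sorted by
    gene; components with fewer than 3 nodes contribute zeros.
    """
    rows = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        n = sub.number_of_nodes()
        raw = nx.betweenness_centrality(sub, normalized=False)
        denom = (n - 1) * (n - 2) / 2.0
        for node in component:
            rows.append(
                (node, float(raw[node]), float(raw[node] / denom) if n >= 3 else 0.0)
            )
    table = pd.DataFrame(rows, columns=["gene", "raw", "normalized"])
    return table.sort_values("gene").reset_index(drop=True)


def classify_central(table: pd.DataFrame, threshold: float = 0.15) -> list[str]:
    """Genes with normalized betweenness >= threshold, most central first."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError(f"centrality threshold must be in [0, 1], got {threshold}")
    if len(table) == 0:
        raise DomainError("empty centrality table")
    central = table[table["normalized"] >= threshold]
    central = central.sort_values(["normalized", "gene"], ascending=[False, True])
    return list(central["gene"])


def attach_betweenness(graph: nx.Graph, table: pd.DataFrame | None = None) -> nx.Graph:
    """Attach normalized betweenness as a node attribute (for GraphML export)."""
    if table is None:
        table = betweenness(graph)
    values = dict(zip(table["gene"], table["normalized"]))
    nx.set_node_attributes(graph, values, "betweenness")
    return graph
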