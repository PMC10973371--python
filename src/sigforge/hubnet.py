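"""Hub-gene selection from a protein-interaction graph.

Candidate prognostic genes are intersected with a confidence-filtered
STRING-style interaction network and ranked by two centralities: exact
shortest-path betweenness (Brandes accumulation, unnormalized pair counts,
fractional credit for tied shortest paths) and radiality in the Scardoni
form, rad(v) = sum_u (diam + 1 - d(v, u)) / (m - 1) taken within each
connected component of size m and diameter diam. The hub list is the union
of the top-k genes under each ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .datatypes import EdgeList, ValidationError

log = logging.getLogger("sigforge")


def build_graph(edges: EdgeList, restrict_to: list[str] | None = None) -> nx.Graph:
    """Undirected graph from an edge list, optionally induced on a gene list.

    Requested genes absent from every edge are kept as isolated nodes so
    downstream centralities report them (with score 0).
    """
    g = nx.Graph()
    for a, b in edges.edges[["gene_a", "gene_b"]].itertuples(index=False):
        g.add_edge(a, b)
    if restrict_to is None:
        return g
    keep = set(restrict_to)
    found = keep & set(g.nodes)
    if not found:
        raise ValidationError("no requested gene appears in the edge list")
    dropped = len(keep) - len(found)
    if dropped:
        log.info("%d requested genes absent from the edge list; kept as queried", dropped)
    sub = g.subgraph(found).copy()
    sub.add_nodes_from(keep - found)  # isolated, degree 0
    return sub


def betweenness(graph: nx.Graph) -> pd.Series:
    """Unnormalized shortest-path betweenness (pairs counted once)."""
    bc = nx.betweenness_centrality(graph, normalized=False)
    return pd.Series(bc, dtype=float).sort_index()


def radiality(graph: nx.Graph) -> pd.Series:
    """Scardoni radiality per connected component; singletons score 0."""
    rad = {n: 0.0 for n in graph.nodes}
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        m = len(nodes)
        if m == 1:
            continue
        sub = graph.subgraph(nodes)
        dist = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(d for row in dist.values() for d in row.values())
        for v in nodes:
            total = sum(diam + 1 - dist[v][u] for u in nodes if u != v)
            rad[v] = total / (m - 1)
    return pd.Series(rad, dtype=float).sort_index()


def centrality_table(graph: nx.Graph) -> pd.DataFrame:
    """Betweenness and radiality side by side, indexed by gene."""
    return pd.DataFrame({"betweenness": betweenness(graph), "radiality": radiality(graph)})


@dataclass
class HubSelection:
    """Union of top-k genes by betweenness and by radiality."""

    hubs: list[str]
    from_betweenness: list[str]
    from_radiality: list[str]
    k: int

    def provenance(self) -> pd.DataFrame:
        rows = []
        for g in self.hubs:
            rows.append(
                {
                    "gene": g,
                    "top_betweenness": g in self.from_betweenness,
                    "top_radiality": g in self.from_radiality,
                }
            )
        return pd.DataFrame(rows)


def _top_k(primary: pd.Series, secondary: pd.Series, k: int) -> list[str]:
    # rank by primary score; ties by the other centrality, then gene ID
    order = sorted(primary.index, key=lambda g: (-primary[g], -secondary[g], g))
    return order[:k]


def select_hubs(centralities: pd.DataFrame, k: int = 10) -> HubSelection:
    """Union of the top-k genes under each centrality ranking.

    Ties at the k-th rank break by the other centrality and then by gene ID,
    so the selection is deterministic. The result has between k and 2k genes.
    """
    if k > len(centralities):
        raise ValidationError(f"k={k} exceeds node count {len(centralities)}")
    bt, rd = centralities["betweenness"], centralities["radiality"]
    top_b = _top_k(bt, rd, k)
    top_r = _top_k(rd, bt, k)
    hubs = sorted(set(top_b) | set(top_r))
    return HubSelection(hubs=hubs, from_betweenness=top_b, from_radiality=top_r, k=k)
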