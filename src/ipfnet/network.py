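"""Disease-module construction on a protein interactome.

DEGs are projected onto the interactome as an induced subgraph; its
largest connected component is the disease module on which centralities
are computed and hub genes (top decile of degree, closeness and
betweenness simultaneously) are called.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

logger = logging.getLogger("ipfnet")


def project_module(genes: set[str], interactome: nx.Graph) -> nx.Graph:
    """Induced subgraph of the interactome on the given genes.

    Isolated nodes are retained; the count of genes with at least one
    link is logged.
    """
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in interactome]
    if not present:
        raise ValueError("no gene maps to the interactome")
    sub = interactome.subgraph(present).copy()
    linked = sum(1 for n in sub.nodes if sub.degree(n) >= 1)
    logger.info("project_module: %d/%d genes mapped, %d with >=1 link", len(present), len(genes), linked)
    return sub


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Connected component with most nodes; ties broken by the component
    containing the lexicographically smallest node."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(graph))
    max_size = max(len(c) for c in comps)
    # among max-size components pick the one with the smallest member node
    best = min((c for c in comps if len(c) == max_size), key=min)
    return graph.subgraph(best).copy()


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, closeness and betweenness per node with per-measure ranks.

    Closeness uses within-component normalisation ``(n_c - 1) / sum of
    distances`` (0 for singletons); betweenness is Brandes' exact count,
    unnormalised, endpoints excluded.  Rank 1 = highest value; ties are
    broken by gene name ascending.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need a graph with >= 2 nodes")
    deg = dict(graph.degree())
    clo = nx.closeness_centrality(graph, wf_improved=False)
    bet = nx.betweenness_centrality(graph, normalized=False)
    n_single = sum(1 for n in graph.nodes if deg[n] == 0)
    if n_single:
        logger.info("centralities: %d singleton node(s) assigned closeness 0", n_single)
    out = pd.DataFrame(
        {
            "degree": pd.Series(deg, dtype=float),
            "closeness": pd.Series(clo),
            "betweenness": pd.Series(bet),
        }
    ).sort_index()
    for col in ("degree", "closeness", "betweenness"):
        order = sorted(out.index, key=lambda g: (-out.at[g, col], g))
        out[f"{col}_rank"] = pd.Series(
            {g: r + 1 for r, g in enumerate(order)}
        )
    return out


def hub_genes(table: pd.DataFrame, top_frac: float = 0.10) -> set[str]:
    """Genes in the top ``top_frac`` of all three centralities.

    Per measure, the ``ceil(top_frac * n)`` highest-ranked nodes are
    taken (name-ascending tie-break already baked into the ranks); hubs
    are the intersection of the three top sets.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    if not 0 < top_frac < 1:
        if top_frac >= 1:
            return set(table.index)
        raise ValueError("top_frac must be in (0, 1)")
    k = math.ceil(top_frac * len(table))
    tops = []
    for col in ("degree", "closeness", "betweenness"):
        tops.append(set(table.sort_values(f"{col}_rank").index[:k]))
    hubs = tops[0] & tops[1] & tops[2]
    return hubs
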