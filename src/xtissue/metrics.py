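"""Centrality tables and the family-level network with enrichment scores.

Betweenness centrality (unweighted shortest paths, normalized to [0, 1])
prioritizes genes sitting between tissue clusters; degree tables surface
local hubs.  At the family level, edges between gene families are counted
and scored with an upper-tail hypergeometric test — "did these two
families attract more network edges than chance, given their sizes and the
total edge budget?" — with score = -log10(p).
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .core import GeneSetCatalog, XTissueError

log = logging.getLogger(__name__)


def betweenness(net: nx.Graph) -> pd.DataFrame:
    """Normalized unweighted betweenness and degree per node.

    Normalization divides each node's path count by (n-1)(n-2)/2, the
    undirected convention; graphs with fewer than 3 nodes get all zeros.
    Computed on the full graph (no per-component renormalization).
    """
    if net.number_of_nodes() < 3:
        bc = {g: 0.0 for g in net.nodes}
    else:
        bc = nx.betweenness_centrality(net, normalized=True)
    table = pd.DataFrame(
        {
            "gene": sorted(net.nodes),
            "betweenness": [bc[g] for g in sorted(net.nodes)],
            "degree": [net.degree(g) for g in sorted(net.nodes)],
        }
    ).set_index("gene")
    return table.sort_values(
        ["betweenness", "gene"], ascending=[False, True]
    )


def degree_table(net: nx.Graph, report_threshold: int = 30) -> pd.DataFrame:
    """Per-node degree, with a ``reported`` flag for degree > threshold."""
    table = pd.DataFrame(
        {
            "gene": sorted(net.nodes),
            "degree": [net.degree(g) for g in sorted(net.nodes)],
        }
    ).set_index("gene")
    table["reported"] = table["degree"] > report_threshold
    return table.sort_values(["degree", "gene"], ascending=[False, True])


def family_group(catalog: GeneSetCatalog, gene: str) -> str:
    """Grouping used by the family network.

    SLC and ABC genes group by family; DMEs pool into Phase 1 / Phase 2.
    Genes outside those classes have no group.
    """
    if gene not in catalog.table.index:
        raise XTissueError(f"gene {gene!r} not in catalog; no family group")
    cls = catalog.class_of(gene)
    if cls in ("SLC", "ABC"):
        return catalog.family_of(gene)
    if cls == "DME_phase1":
        return "DME Phase 1"
    if cls == "DME_phase2":
        return "DME Phase 2"
    raise XTissueError(f"gene {gene!r} (class {cls}) has no family group")


def family_edge_counts(
    net: nx.Graph, catalog: GeneSetCatalog
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Edge counts between family groups, plus group sizes in the network.

    Returns ``(counts, sizes)`` where counts has columns ``group1``,
    ``group2`` (``group1 <= group2``; equal for within-group counts) and
    ``count``.  Every network gene must have a group.
    """
    ungrouped = []
    groups = {}
    for g in net.nodes:
        try:
            groups[g] = family_group(catalog, g)
        except XTissueError:
            ungrouped.append(g)
    if ungrouped:
        raise XTissueError(
            f"network genes without a family group: {sorted(ungrouped)}"
        )
    sizes: dict[str, int] = {}
    for g, grp in groups.items():
        sizes[grp] = sizes.get(grp, 0) + 1
    counts: dict[tuple[str, str], int] = {}
    for u, v in net.edges:
        key = tuple(sorted((groups[u], groups[v])))
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"group1": a, "group2": b, "count": c}
        for (a, b), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["group1", "group2", "count"]), sizes


def family_hyper_score(
    x: int, size_a: int, size_b: int, E: int, N: int, within: bool = False
) -> float:
    """-log10 upper-tail hypergeometric probability of >= x family edges.

    The population is the N possible gene pairs of the network, of which E
    became edges; the family pair contributes K = size_a * size_b candidate
    pairs (or C(size_a, 2) within a family).  Computed through the
    log-survival function for numerical stability.
    """
    K = math.comb(size_a, 2) if within else size_a * size_b
    if not 0 <= x <= min(K, E):
        raise XTissueError(
            f"inconsistent counts: x={x}, K={K}, E={E}"
        )
    if E > N or K > N:
        raise XTissueError(f"draws/successes exceed population: E={E}, K={K}, N={N}")
    if x == 0:
        return 0.0
    logp = hypergeom.logsf(x - 1, N, K, E)
    return float(-logp / math.log(10.0))


def family_scores(
    counts: pd.DataFrame,
    sizes: dict[str, int],
    n_edges: int,
    n_nodes: int,
) -> pd.DataFrame:
    """Attach hypergeometric scores to a family edge-count table."""
    N = math.comb(n_nodes, 2)
    scores = []
    for row in counts.itertuples(index=False):
        within = row.group1 == row.group2
        scores.append(
            family_hyper_score(
                row.count,
                sizes[row.group1],
                sizes[row.group2],
                n_edges,
                N,
                within=within,
            )
        )
    out = counts.copy()
    out["hyper_score"] = scores
    return out


def build_family_network(
    scored: pd.DataFrame,
    score_threshold: float = 2.0,
    include_within: bool = False,
) -> nx.Graph:
    """Family network keeping edges with hyper_score above the threshold.

    A score threshold of 2.0 corresponds to p < 0.01.  Within-group counts
    are computed upstream but excluded from the displayed network unless
    ``include_within``.  Node attribute ``significant_degree`` counts
    retained incident edges.
    """
    fam = nx.Graph()
    for row in scored.itertuples(index=False):
        fam.add_node(row.group1)
        fam.add_node(row.group2)
    for row in scored.itertuples(index=False):
        if row.group1 == row.group2 and not include_within:
            continue
        if row.hyper_score > score_threshold:
            fam.add_edge(
                row.group1,
                row.group2,
                edge_count=int(row.count),
                hyper_score=float(row.hyper_score),
            )
    for node in fam.nodes:
        fam.nodes[node]["significant_degree"] = fam.degree(node)
    return fam
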