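"""ADME annotation, the remote sensing and signaling (RSS) network, and
the knockout/ChIP validation overlap statistic.

The RSS network is the ADME-gene-centered view of the PPI-filtered
gut-liver-kidney network: curated core/extended/related ADME genes found
in the network, plus their first neighbors, with only edges that are both
co-expressed and PPI-supported.  Betweenness on this network prioritizes
genes carrying inter-organ connectivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

import pandas as pd

from .core import GeneSetCatalog, XTissueError
from .coexpression import CorrelationMatrix
from .expansion import EdgeRule, rank_paired_tissue, rank_single_tissue, tissue_connection_counts
from .metrics import betweenness

log = logging.getLogger(__name__)

ADME_SEED_STATUSES = ("core", "extended", "related")

#: node shape encoding by ADME role, for downstream visualization
NODE_SHAPES = {
    "core": "triangle-large",
    "extended": "triangle-small",
    "related": "square",
    "neighbor": "circle",
}


def annotate_adme(net: nx.Graph, catalog: GeneSetCatalog) -> dict[str, int]:
    """Set per-node ``adme_status`` from the catalog; return status counts."""
    counts = {s: 0 for s in ("core", "extended", "related", "none")}
    for g in net.nodes:
        status = catalog.status_of(g)
        net.nodes[g]["adme_status"] = status
        counts[status] += 1
    log.info("ADME statuses in network: %s", counts)
    return counts


def build_rss_network(net: nx.Graph) -> nx.Graph:
    """ADME seeds plus first neighbors in a PPI-filtered network.

    ``net`` must already carry ``adme_status`` node attributes and have
    been PPI-filtered (its edges are both co-expressed and PPI-supported).
    Seeds are genes with status core/extended/related; the node set is the
    depth-1 closure of the seeds, the edge set all of ``net``'s edges among
    those nodes.  Seeds isolated in ``net`` are retained.  Node ``shape``
    encodes the ADME role; betweenness and degree are recomputed on the
    result.
    """
    seeds = [
        g
        for g in net.nodes
        if net.nodes[g].get("adme_status", "none") in ADME_SEED_STATUSES
    ]
    if not seeds:
        raise XTissueError("no ADME genes present in the network")
    members = set(seeds)
    for s in seeds:
        members.update(net.neighbors(s))
    rss = net.subgraph(sorted(members)).copy()
    for g in rss.nodes:
        status = rss.nodes[g].get("adme_status", "none")
        rss.nodes[g]["shape"] = NODE_SHAPES.get(status, NODE_SHAPES["neighbor"])
        rss.nodes[g]["is_seed"] = status in ADME_SEED_STATUSES
    table = betweenness(rss)
    for g in rss.nodes:
        rss.nodes[g]["betweenness"] = float(table.at[g, "betweenness"])
        rss.nodes[g]["degree"] = int(table.at[g, "degree"])
    return rss


def top_connected_transcriptome(
    corr_full: CorrelationMatrix,
    glk_genes_by_tissue: dict[str, list[str]],
    edge_rule: EdgeRule,
    top_m: int = 100,
) -> pd.DataFrame:
    """Transcriptome-wide genes most connected to the GLK network.

    The union of (a) the ``top_m`` genes by single-tissue connection count
    for each focus tissue and (b) the ``top_m`` by paired-tissue
    (min-of-pair) score for each tissue pair, over all non-GLK genes in
    the correlation universe.  Returns a gene-indexed DataFrame whose
    ``sources`` column records which rankings selected each gene.
    """
    glk_all = {g for gs in glk_genes_by_tissue.values() for g in gs}
    candidates = sorted(set(corr_full.gene_ids) - glk_all)
    if not candidates:
        return pd.DataFrame(columns=["sources"]).rename_axis("gene")
    counts = tissue_connection_counts(
        corr_full, glk_genes_by_tissue, candidates, edge_rule
    )
    sources: dict[str, list[str]] = {}
    tissues = sorted(glk_genes_by_tissue)
    for t in tissues:
        for g in rank_single_tissue(counts, t, top_m)["gene"]:
            sources.setdefault(g, []).append(f"single:{t}")
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i + 1 :]:
            for g in rank_paired_tissue(counts, (t1, t2), top_m)["gene"]:
                sources.setdefault(g, []).append(f"paired:{t1}-{t2}")
    out = pd.DataFrame(
        {"gene": sorted(sources), "sources": [",".join(sources[g]) for g in sorted(sources)]}
    ).set_index("gene")
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Wet-lab support for computationally associated genes."""

    n_associated: int
    n_supported: int
    percent: float  # 100 * supported / associated, 1 decimal


def validation_overlap(
    associated: int | set | frozenset | list,
    supported: int | set | frozenset | list,
) -> OverlapResult:
    """Percent of associated genes supported by independent evidence.

    Accepts gene sets (support must be a subset of the associated set) or
    already de-duplicated counts.  The percent is rounded to one decimal.
    """
    if isinstance(associated, (set, frozenset, list)):
        a_set = set(associated)
        if not isinstance(supported, (set, frozenset, list)):
            raise XTissueError("mixed set/count arguments")
        s_set = set(supported)
        extra = s_set - a_set
        if extra:
            raise XTissueError(
                f"supported genes outside associated set: {sorted(extra)[:5]}"
            )
        n_a, n_s = len(a_set), len(s_set)
    else:
        n_a, n_s = int(associated), int(supported)
        if n_s > n_a:
            raise XTissueError("supported count exceeds associated count")
    if n_a == 0:
        raise XTissueError("associated set is empty")
    return OverlapResult(n_a, n_s, round(100.0 * n_s / n_a, 1))
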