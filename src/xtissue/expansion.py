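"""Connectivity ranking of outside genes, network expansion and PPI filtering.

Candidate genes (outside the focal transporter/DME set) are ranked by how
many gut-, liver- or kidney-assigned focal genes they are co-expressed
with.  Single-tissue rankings sort on one tissue's count; paired-tissue
rankings sort on the minimum of the two counts, recovering genes connected
to *both* tissues rather than just one.  Top-ranked genes are added to the
network, and edges are then filtered by presence in a protein-protein
interaction network to prioritize likely physical interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import PPINetwork, TissueProfile, XTissueError
from .coexpression import CorrelationMatrix
from .tissue import assign_edge_tissue

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeRule:
    """Adjacency criterion for candidate x focal pairs.

    ``threshold`` keeps pairs with r strictly above ``value``; ``top_k``
    keeps the k highest-r candidate pairs jointly.
    """

    mode: str  # "threshold" | "top_k"
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "top_k"):
            raise XTissueError(f"unknown edge rule mode {self.mode!r}")


def _adjacency(
    corr_full: CorrelationMatrix,
    rows: list[str],
    cols: list[str],
    rule: EdgeRule,
) -> np.ndarray:
    """Boolean rows x cols adjacency under the edge rule (NaN-safe)."""
    sub = corr_full.data.loc[rows, cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if rule.mode == "threshold":
            return sub > rule.value
        k = int(rule.value)
        flat = sub.ravel()
        defined = ~np.isnan(flat)
        adj = np.zeros(flat.shape, dtype=bool)
        if k >= defined.sum():
            adj[defined] = True
        else:
            idx = np.flatnonzero(defined)
            vals = flat[idx]
            cut = np.partition(vals, len(vals) - k)[len(vals) - k]
            adj[idx[vals >= cut]] = True
        return adj.reshape(sub.shape)


def tissue_connection_counts(
    corr_full: CorrelationMatrix,
    glk_genes_by_tissue: dict[str, list[str]],
    candidates: list[str],
    edge_rule: EdgeRule,
) -> pd.DataFrame:
    """Per-candidate, per-tissue counts of connections to GLK focal genes.

    ``glk_genes_by_tissue`` maps each focus tissue to the focal genes
    assigned to it.  Candidates must be disjoint from those genes.
    Returns a candidates x tissues integer DataFrame.
    """
    candidates = sorted(set(candidates))
    focal_all = {g for gs in glk_genes_by_tissue.values() for g in gs}
    overlap = focal_all & set(candidates)
    if overlap:
        raise XTissueError(
            f"candidates overlap GLK genes: {sorted(overlap)[:5]}"
        )
    tissues = sorted(glk_genes_by_tissue)
    counts = pd.DataFrame(0, index=candidates, columns=tissues, dtype=int)
    for t in tissues:
        focal = sorted(glk_genes_by_tissue[t])
        if not focal:
            continue
        adj = _adjacency(corr_full, candidates, focal, edge_rule)
        counts[t] = adj.sum(axis=1)
    return counts


def rank_single_tissue(
    table: pd.DataFrame, tissue: str, top_n: int
) -> pd.DataFrame:
    """Top candidates by connection count to one tissue (ties by gene id)."""
    if tissue not in table.columns:
        raise XTissueError(f"tissue {tissue!r} not in count table")
    out = table[[tissue]].rename(columns={tissue: "count"})
    out = out.rename_axis("gene").reset_index()
    out = out.sort_values(
        ["count", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
    return out.head(top_n)


def rank_paired_tissue(
    table: pd.DataFrame, pair: tuple[str, str], top_n: int = 20
) -> pd.DataFrame:
    """Top candidates by min(count_t1, count_t2).

    Ties are broken by the total count over the pair, then by gene id.
    """
    t1, t2 = pair
    for t in pair:
        if t not in table.columns:
            raise XTissueError(f"tissue {t!r} not in count table")
    out = pd.DataFrame(
        {
            "gene": table.index,
            "score": table[[t1, t2]].min(axis=1).to_numpy(),
            "total": (table[t1] + table[t2]).to_numpy(),
        }
    )
    out = out.sort_values(
        ["score", "total", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out.head(top_n)


def expand_network(
    glk_net: nx.Graph,
    expansion_genes: list[str],
    corr_full: CorrelationMatrix,
    edge_rule: EdgeRule,
    profile: TissueProfile,
    focus_tissues: tuple[str, ...] | None = None,
) -> nx.Graph:
    """Add expansion genes and their qualifying edges to the GLK network.

    New edges connect expansion genes to original nodes and to each other
    wherever the edge rule holds; each new edge is labeled by the tissue of
    highest shared expression.  Node ``provenance`` distinguishes
    ``"core"`` (original) from ``"expansion"`` nodes.
    """
    missing = [g for g in expansion_genes if g not in corr_full.data.index]
    if missing:
        raise XTissueError(f"expansion genes absent from correlation: {missing}")
    net = glk_net.copy()
    for g in net.nodes:
        net.nodes[g].setdefault("provenance", "core")
    new = sorted(set(expansion_genes) - set(glk_net.nodes))
    if not new:
        return net
    targets = sorted(set(glk_net.nodes) | set(new))
    adj = _adjacency(corr_full, new, targets, edge_rule)
    tindex = {g: j for j, g in enumerate(targets)}
    for g in new:
        net.add_node(g, provenance="expansion")
    for i, g in enumerate(new):
        for t in targets:
            if t == g or (t in new and t <= g):
                continue  # expansion-pair handled once, no self loops
            if adj[i, tindex[t]]:
                label, argmax = assign_edge_tissue(profile, (g, t), focus_tissues)
                net.add_edge(
                    g,
                    t,
                    correlation=float(corr_full.data.at[g, t]),
                    tissue=label,
                    tissue_argmax=argmax,
                )
    return net


def ppi_filter(net: nx.Graph, ppi: PPINetwork) -> nx.Graph:
    """Keep only co-expression edges also present in the PPI network.

    The node set is unchanged: genes isolated by the filter stay in the
    graph (flagged ``isolated_after_ppi``) so downstream centrality sees
    them as zero rather than silently shrinking the universe.
    """
    out = net.copy()
    drop = [(u, v) for u, v in out.edges if (u, v) not in ppi]
    out.remove_edges_from(drop)
    for g in out.nodes:
        out.nodes[g]["isolated_after_ppi"] = out.degree(g) == 0
    log.info(
        "PPI filter: %d -> %d edges (%d nodes retained)",
        net.number_of_edges(),
        out.number_of_edges(),
        out.number_of_nodes(),
    )
    return out
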