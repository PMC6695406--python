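"""Tissue assignment, cluster proximity and the GLK edge-fraction statistic.

Every gene is assigned the grouped tissue in which its mean expression is
highest; every edge the tissue maximizing the unweighted mean of its two
endpoints' profiles.  Counting edges between tissue assignments gives the
cluster proximity matrix, whose hierarchically ordered heatmap exposes the
gut-liver-kidney cluster.  The edge-fraction statistic quantifies how
concentrated a gene set's strongest co-expression edges are in the focus
tissues, against size-matched random and control-class samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .core import TissueProfile, XTissueError
from .coexpression import CorrelationMatrix, select_edges

log = logging.getLogger(__name__)

#: assignment label for all-zero genes (excluded from proximity counts)
UNDETERMINED = "undetermined"


def assign_gene_tissue(profile: TissueProfile, gene: str) -> str:
    """Tissue of highest mean expression; lexicographic tie-break.

    All-zero genes get the label ``"undetermined"``.
    """
    if gene not in profile.data.index:
        raise XTissueError(f"gene {gene!r} absent from profile")
    row = profile.data.loc[gene]
    if (row == 0).all():
        log.warning("gene %s has all-zero profile; tissue undetermined", gene)
        return UNDETERMINED
    top = row.max()
    candidates = sorted(row.index[row == top])
    if len(candidates) > 1:
        log.info("tissue tie for %s: %s -> %s", gene, candidates, candidates[0])
    return candidates[0]


def assign_tissues(
    profile: TissueProfile, genes: list[str] | None = None
) -> pd.Series:
    """Vectorized gene -> tissue assignment for many genes."""
    data = profile.data if genes is None else profile.data.loc[genes]
    values = data.to_numpy(dtype=float)
    tissues = np.asarray(data.columns)
    order = np.argsort(tissues, kind="stable")
    values = values[:, order]  # lexicographic column order => ties resolve low
    tissues = tissues[order]
    labels = tissues[np.argmax(values, axis=1)].astype(object)
    labels[(values == 0).all(axis=1)] = UNDETERMINED
    return pd.Series(labels, index=data.index, name="tissue")


def assign_edge_tissue(
    profile: TissueProfile,
    edge: tuple[str, str],
    focus_tissues: tuple[str, ...] | None = None,
) -> tuple[str, str]:
    """Label an edge with the tissue of highest shared expression.

    The argmax is over the unweighted mean of the two endpoint profiles,
    ties broken lexicographically.  Returns ``(label, argmax)`` where
    ``label`` is ``"other"`` when the argmax tissue is outside
    ``focus_tissues`` (if a focus list is given).
    """
    g1, g2 = edge
    for g in (g1, g2):
        if g not in profile.data.index:
            raise XTissueError(f"gene {g!r} absent from profile")
    mean = (profile.data.loc[g1] + profile.data.loc[g2]) / 2.0
    if (mean == 0).all():
        return UNDETERMINED, UNDETERMINED
    top = mean.max()
    argmax = sorted(mean.index[mean == top])[0]
    if focus_tissues is not None and argmax not in focus_tissues:
        return "other", argmax
    return argmax, argmax


def annotate_network_tissues(
    net: nx.Graph,
    profile: TissueProfile,
    focus_tissues: tuple[str, ...] | None = None,
) -> nx.Graph:
    """Set node ``tissue`` and edge ``tissue``/``tissue_argmax`` attributes in place."""
    gene_tissue = assign_tissues(profile, sorted(net.nodes))
    sub = profile.data.loc[sorted(net.nodes)]
    tissues = np.asarray(sorted(sub.columns))
    values = sub[tissues].to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(sub.index)}
    for g in net.nodes:
        net.nodes[g]["tissue"] = gene_tissue[g]
    for u, v in net.edges:
        mean = (values[index[u]] + values[index[v]]) / 2.0
        if (mean == 0).all():
            label = argmax = UNDETERMINED
        else:
            argmax = tissues[int(np.argmax(mean))]
            label = (
                "other"
                if focus_tissues is not None and argmax not in focus_tissues
                else argmax
            )
        net.edges[u, v]["tissue"] = label
        net.edges[u, v]["tissue_argmax"] = argmax
    return net


def cluster_proximity(
    net: nx.Graph,
    assignment: pd.Series,
    tissues: list[str] | None = None,
) -> pd.DataFrame:
    """Tissue x tissue counts of edges by endpoint tissue assignment.

    Each edge is counted once; the matrix is symmetric with within-tissue
    edges on the diagonal.  Edges with an undetermined endpoint are
    excluded (warned).  ``tissues`` fixes the row/column universe (e.g.,
    all profile tissues, leaving zero rows for tissues without network
    genes); by default only tissues assigned to network genes appear.
    """
    missing = [g for g in net.nodes if g not in assignment.index]
    if missing:
        raise XTissueError(f"assignment missing for genes: {missing[:5]}")
    if tissues is None:
        tissues = sorted(
            t
            for t in assignment.loc[list(net.nodes)].unique()
            if t != UNDETERMINED
        )
    else:
        tissues = sorted(set(tissues) - {UNDETERMINED})
        seen = set(assignment.loc[list(net.nodes)].unique()) - {UNDETERMINED}
        if not seen <= set(tissues):
            raise XTissueError(
                f"assigned tissues outside universe: {sorted(seen - set(tissues))}"
            )
    prox = pd.DataFrame(0, index=tissues, columns=tissues, dtype=int)
    n_skipped = 0
    for u, v in net.edges:
        t1, t2 = assignment[u], assignment[v]
        if UNDETERMINED in (t1, t2):
            n_skipped += 1
            continue
        prox.loc[t1, t2] += 1
        if t1 != t2:
            prox.loc[t2, t1] += 1
    if n_skipped:
        log.warning("%d edges skipped (undetermined tissue)", n_skipped)
    return prox


def proximity_total(prox: pd.DataFrame) -> int:
    """Sum of the upper triangle plus diagonal (= number of counted edges)."""
    values = prox.to_numpy()
    return int(np.triu(values).sum())


@dataclass(frozen=True)
class HierarchicalOrder:
    """Dendrogram leaf order and merge tree over proximity-matrix tissues."""

    tissues: list[str]  # leaf order
    linkage: np.ndarray  # scipy linkage matrix over ``labels``
    labels: list[str]  # input order indexing the linkage


def hierarchical_order(prox: pd.DataFrame) -> HierarchicalOrder:
    """Average-linkage clustering of proximity rows, distance = 1 - Pearson r.

    Constant rows have undefined correlations; their distance to every
    other tissue is set to the maximum (2.0, logged).
    """
    labels = list(prox.index)
    if len(labels) < 2:
        raise XTissueError("hierarchical ordering needs >= 2 tissues")
    values = prox.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning(
            "constant proximity rows (distance pinned to 2.0): %s",
            [labels[i] for i in np.flatnonzero(constant)],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    dist = 1.0 - corr
    dist[constant, :] = 2.0
    dist[:, constant] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    condensed = dist[np.triu_indices(len(labels), k=1)]
    linkage = sch.linkage(condensed, method="average")
    order = [labels[i] for i in sch.leaves_list(linkage)]
    return HierarchicalOrder(order, linkage, labels)


def first_all_focus_cluster(
    order: HierarchicalOrder, focus_tissues: tuple[str, ...]
) -> tuple[set[str], float] | None:
    """First merge-tree cluster containing every focus tissue.

    Returns ``(member set, merge height)``, or None if the focus tissues
    never co-occur (possible only if some are absent from the matrix).
    """
    focus = set(focus_tissues) & set(order.labels)
    if not focus:
        return None
    clusters: dict[int, set[str]] = {
        i: {t} for i, t in enumerate(order.labels)
    }
    n = len(order.labels)
    for step, (a, b, height, _) in enumerate(order.linkage):
        merged = clusters[int(a)] | clusters[int(b)]
        clusters[n + step] = merged
        if focus <= merged:
            return merged, float(height)
    return None


@dataclass(frozen=True)
class EdgeFractionResult:
    """Fraction of a gene set's top edges labeled with a target tissue."""

    fraction: float
    n_edges: int


def focal_edge_fraction(
    corr_full: CorrelationMatrix,
    focal: list[str],
    k: int,
    profile: TissueProfile,
    target_tissues: tuple[str, ...],
) -> EdgeFractionResult:
    """Fraction of the top-k edges among ``focal`` pairs mapping to the targets.

    Edges are labeled by the tissue of highest shared expression (the
    unrestricted argmax); the fraction is over the realized edge count.
    """
    if k < 1:
        raise XTissueError("k must be >= 1")
    sub = corr_full.subset(sorted(set(focal)))
    edges = select_edges(sub, "top_k", k)
    if len(edges) == 0:
        raise XTissueError("no defined focal pairs to select edges from")
    data = profile.data.loc[sorted(set(focal))]
    tissues = np.asarray(sorted(data.columns))
    values = data[tissues].to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(data.index)}
    hits = 0
    targets = set(target_tissues)
    for row in edges.itertuples(index=False):
        mean = (values[index[row.gene1]] + values[index[row.gene2]]) / 2.0
        if (mean == 0).all():
            continue
        if tissues[int(np.argmax(mean))] in targets:
            hits += 1
    log.info("edge fraction over %d realized edges", len(edges))
    return EdgeFractionResult(hits / len(edges), len(edges))


@dataclass(frozen=True)
class ControlFractions:
    """Edge-fraction distribution over size-matched random gene samples."""

    mean: float
    sd: float  # population sd over the replicate fractions
    samples: tuple[float, ...]


def control_fractions(
    corr_full: CorrelationMatrix,
    pool: list[str],
    size: int,
    k: int,
    profile: TissueProfile,
    target_tissues: tuple[str, ...],
    reps: int = 10,
    seed: int = 0,
) -> ControlFractions:
    """Edge fractions of ``reps`` uniform without-replacement samples from ``pool``."""
    pool = sorted(set(pool))
    if size > len(pool):
        raise XTissueError(
            f"sample size {size} exceeds pool size {len(pool)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    fractions = []
    for _ in range(reps):
        sample = list(rng.choice(pool, size=size, replace=False))
        res = focal_edge_fraction(corr_full, sample, k, profile, target_tissues)
        fractions.append(res.fraction)
    arr = np.asarray(fractions)
    return ControlFractions(float(arr.mean()), float(arr.std(ddof=0)), tuple(fractions))
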