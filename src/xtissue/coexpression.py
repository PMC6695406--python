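"""Tissue averaging, cross-tissue correlation and edge selection.

The central statistic is Pearson's r between the tissue-mean expression
profiles of two genes, interpreted as the tendency of the pair to be
expressed in similar sets of tissues.  The network keeps either the top-k
most correlated pairs or all pairs above a correlation floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneSetCatalog,
    SampleDesign,
    TissueProfile,
    XTissueError,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric gene-gene Pearson correlation matrix.

    Zero-variance genes have undefined correlations; they are listed in
    ``undefined`` and carry NaN rows/columns, and are excluded from edge
    selection.
    """

    data: pd.DataFrame
    undefined: frozenset[str] = frozenset()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, genes: list[str]) -> "CorrelationMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise XTissueError(f"genes absent from correlation: {missing}")
        sub = self.data.loc[genes, genes]
        return CorrelationMatrix(
            sub, frozenset(g for g in self.undefined if g in genes)
        )


def average_by_tissue(
    expr: ExpressionMatrix, design: SampleDesign
) -> TissueProfile:
    """Arithmetic mean of expression over the samples of each grouped tissue."""
    design.require_samples(expr.sample_ids)
    tissue = design.tissue.loc[expr.sample_ids]
    means = expr.data.T.groupby(tissue).mean().T
    means = means[sorted(means.columns)]
    return TissueProfile(means)


def cross_tissue_correlation(
    profile: TissueProfile,
    genes: list[str] | None = None,
    log_transform: bool = False,
) -> CorrelationMatrix:
    """Pearson correlation of gene profiles across the tissue dimension.

    With ``log_transform`` the profile is mapped through ``log2(x + 1)``
    first.  Requires at least 3 tissues.  Zero-variance genes are flagged
    undefined rather than correlated.
    """
    data = profile.data
    if genes is not None:
        missing = [g for g in genes if g not in data.index]
        if missing:
            raise XTissueError(f"genes absent from profile: {missing}")
        data = data.loc[genes]
    if data.shape[1] < 3:
        raise XTissueError("correlation needs at least 3 tissues")
    values = data.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    sd = values.std(axis=1)
    flat = sd == 0
    undefined = frozenset(data.index[flat])
    if undefined:
        log.warning(
            "%d zero-variance genes excluded from correlation", len(undefined)
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    df = pd.DataFrame(corr, index=data.index, columns=data.index)
    return CorrelationMatrix(df, undefined)


def select_edges(
    corr: CorrelationMatrix, mode: str, value: float
) -> pd.DataFrame:
    """Select network edges from a correlation matrix.

    ``top_k`` keeps the k highest-correlation defined pairs, ordered by
    descending r then lexicographic pair; ties that straddle the cut are
    all included (the realized count is logged).  ``threshold`` keeps all
    pairs with r strictly above ``value``.

    Returns a DataFrame with columns ``gene1``, ``gene2``, ``r`` where
    ``gene1 < gene2``.
    """
    genes = np.asarray(corr.gene_ids)
    order = np.argsort(genes, kind="stable")
    genes = genes[order]  # lexicographic gene order for stable tie-breaks
    mat = corr.data.to_numpy()[np.ix_(order, order)]
    iu, ju = np.triu_indices(len(genes), k=1)
    r = mat[iu, ju]
    defined = ~np.isnan(r)
    iu, ju, r = iu[defined], ju[defined], r[defined]

    if mode == "threshold":
        if not -1 < value < 1:
            raise XTissueError("threshold must lie in (-1, 1)")
        keep = r > value
        iu, ju, r = iu[keep], ju[keep], r[keep]
    elif mode == "top_k":
        k = int(value)
        if k <= 0:
            raise XTissueError("top_k edge count must be positive")
        if k < len(r):
            # kth-largest r, then include every pair tied with it
            cut = np.partition(r, len(r) - k)[len(r) - k]
            keep = r >= cut
            iu, ju, r = iu[keep], ju[keep], r[keep]
            if len(r) != k:
                log.info(
                    "top_k boundary ties: realized %d edges for k=%d",
                    len(r),
                    k,
                )
    else:
        raise XTissueError(f"unknown edge selection mode {mode!r}")

    df = pd.DataFrame(
        {"gene1": genes[iu], "gene2": genes[ju], "r": r}
    )
    df = df.sort_values(
        ["r", "gene1", "gene2"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df


def subset_correlation(
    corr: CorrelationMatrix, catalog: GeneSetCatalog, classes: set[str]
) -> CorrelationMatrix:
    """Restrict the matrix to genes of the given classes (intersection)."""
    wanted = catalog.genes_of_classes(classes)
    present = [g for g in corr.gene_ids if g in set(wanted)]
    if not present:
        raise XTissueError(
            f"no genes of classes {sorted(classes)} present in correlation"
        )
    log.info("retained %d genes of classes %s", len(present), sorted(classes))
    return corr.subset(present)


def select_focal_edges(
    corr_full: CorrelationMatrix,
    catalog: GeneSetCatalog,
    classes: set[str],
    mode: str,
    value: float,
    order: str = "subset_first",
) -> pd.DataFrame:
    """Edge selection restricted to focal-class genes, in either order.

    ``subset_first`` (default) restricts to focal genes and then selects
    edges among focal pairs — the order consistent with a focal network of
    exactly k edges.  ``select_first`` selects genome-wide and then drops
    edges with a non-focal endpoint, which can only yield fewer edges.
    """
    if order == "subset_first":
        return select_edges(subset_correlation(corr_full, catalog, classes), mode, value)
    if order == "select_first":
        edges = select_edges(corr_full, mode, value)
        focal = set(catalog.genes_of_classes(classes))
        keep = edges["gene1"].isin(focal) & edges["gene2"].isin(focal)
        return edges[keep].reset_index(drop=True)
    raise XTissueError(f"unknown pipeline order {order!r}")


def build_network(edges: pd.DataFrame, catalog: GeneSetCatalog) -> nx.Graph:
    """Turn an edge list into a co-expression graph with catalog annotations.

    Nodes are the union of edge endpoints (isolated catalog genes are not
    added); edges carry the correlation.
    """
    net = nx.Graph()
    for row in edges.itertuples(index=False):
        net.add_edge(row.gene1, row.gene2, correlation=float(row.r))
    for g in net.nodes:
        if g in catalog.table.index:
            net.nodes[g]["gene_class"] = catalog.class_of(g)
            net.nodes[g]["family"] = catalog.family_of(g)
            net.nodes[g]["adme_status"] = catalog.status_of(g)
    return net
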