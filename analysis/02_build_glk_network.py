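#!/usr/bin/env python
"""Build the focal co-expression network and locate the GLK cluster.

Averages expression by tissue, correlates genes across tissues, keeps the
top 3,000 edges among transporter/DME genes, labels genes and edges by
tissue of highest expression, and writes the network, the tissue-tissue
proximity matrix with its dendrogram ordering, and the GLK edge-fraction
statistic against random and GPCR-like control gene sets.
"""

from pathlib import Path

from xtissue import io
from xtissue.coexpression import (
    average_by_tissue,
    build_network,
    cross_tissue_correlation,
    select_focal_edges,
)
from xtissue.core import FOCAL_CLASSES
from xtissue.simulate import glk_default_config
from xtissue.tissue import (
    annotate_network_tissues,
    assign_tissues,
    cluster_proximity,
    control_fractions,
    first_all_focus_cluster,
    focal_edge_fraction,
    hierarchical_order,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    cfg = glk_default_config(seed=0)
    expr, design = io.read_expression(
        DATA / "expression.tsv", DATA / "design.tsv", tissue_group_map={}
    )
    catalog = io.read_catalog(DATA / "catalog.tsv")
    profile = average_by_tissue(expr, design)
    corr = cross_tissue_correlation(profile)

    edges = select_focal_edges(
        corr, catalog, set(FOCAL_CLASSES), cfg.edge_mode, cfg.edge_value
    )
    net = build_network(edges, catalog)
    annotate_network_tissues(net, profile, cfg.focus_tissues)
    io.write_network(net, ROOT / "focal_network")

    assignment = assign_tissues(profile)
    prox = cluster_proximity(
        net, assignment.loc[sorted(net.nodes)], tissues=profile.tissues
    )
    prox.to_csv(ROOT / "proximity_matrix.csv")
    order = hierarchical_order(prox)
    cluster = first_all_focus_cluster(order, cfg.focus_tissues)

    focal = sorted(
        set(catalog.genes_of_classes(FOCAL_CLASSES)) & set(corr.gene_ids)
    )
    k = int(cfg.edge_value)
    focal_frac = focal_edge_fraction(corr, focal, k, profile, cfg.focus_tissues)
    pool = sorted(set(corr.gene_ids) - set(focal))
    rand = control_fractions(
        corr, pool, len(focal), k, profile, cfg.focus_tissues,
        reps=cfg.control_reps, seed=cfg.seed,
    )
    gpcr = sorted(set(catalog.genes_of_classes({"control"})) & set(corr.gene_ids))
    ctrl = control_fractions(
        corr, gpcr, min(len(focal), len(gpcr)), k, profile, cfg.focus_tissues,
        reps=cfg.control_reps, seed=cfg.seed + 1,
    )

    print(
        f"focal network: {net.number_of_nodes()} genes, {net.number_of_edges()} edges"
    )
    print(f"dendrogram leaf order: {', '.join(order.tissues)}")
    if cluster:
        members, height = cluster
        print(
            f"first cluster containing all focus tissues: {sorted(members)} "
            f"(merge height {height:.3f})"
        )
    print(
        f"GLK edge fraction: focal {focal_frac.fraction:.3f} | "
        f"random {rand.mean:.3f} +/- {rand.sd:.3f} | "
        f"GPCR-like control {ctrl.mean:.3f} +/- {ctrl.sd:.3f}"
    )


if __name__ == "__main__":
    main()
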