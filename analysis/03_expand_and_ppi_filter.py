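#!/usr/bin/env python
"""Expand the GLK network by paired-tissue connectivity and filter by PPI.

Counts each outside gene's co-expression connections (r > 0.59) to the
gut-, liver- and kidney-assigned focal genes, ranks tissue pairs by the
minimum of the two counts, adds the top 20 genes per pair to the network,
and keeps only edges also present in the PPI network.
"""

from pathlib import Path

from xtissue import io
from xtissue.coexpression import average_by_tissue, cross_tissue_correlation
from xtissue.core import FOCAL_CLASSES
from xtissue.expansion import (
    EdgeRule,
    expand_network,
    ppi_filter,
    rank_paired_tissue,
    rank_single_tissue,
    tissue_connection_counts,
)
from xtissue.simulate import glk_default_config
from xtissue.tissue import assign_tissues

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    cfg = glk_default_config(seed=0)
    expr, design = io.read_expression(
        DATA / "expression.tsv", DATA / "design.tsv", tissue_group_map={}
    )
    catalog = io.read_catalog(DATA / "catalog.tsv")
    ppi = io.read_ppi(DATA / "ppi.tsv")
    glk_net = io.read_network(ROOT / "focal_network.graphml")
    # restrict to the genes assigned to the focus tissues
    glk_nodes = [
        g for g in glk_net.nodes if glk_net.nodes[g]["tissue"] in cfg.focus_tissues
    ]
    glk_net = glk_net.subgraph(glk_nodes).copy()

    profile = average_by_tissue(expr, design)
    corr = cross_tissue_correlation(profile)
    assignment = assign_tissues(profile)
    focal = set(catalog.genes_of_classes(FOCAL_CLASSES))
    by_tissue = {
        t: [g for g in glk_nodes if assignment[g] == t]
        for t in cfg.focus_tissues
    }
    candidates = sorted(set(corr.gene_ids) - focal)
    rule = EdgeRule(cfg.expansion_edge_mode, cfg.expansion_edge_value)
    counts = tissue_connection_counts(corr, by_tissue, candidates, rule)
    counts.rename_axis("gene").to_csv(ROOT / "connection_counts.tsv", sep="\t")

    expansion = set()
    tissues = sorted(by_tissue)
    for i, t1 in enumerate(tissues):
        ranking = rank_single_tissue(counts, t1, cfg.transcriptome_top_m)
        ranking.to_csv(ROOT / f"ranking_single_{t1}.tsv", sep="\t", index=False)
        for t2 in tissues[i + 1 :]:
            ranking = rank_paired_tissue(counts, (t1, t2), cfg.expansion_top_n)
            ranking.to_csv(
                ROOT / f"ranking_paired_{t1}_{t2}.tsv", sep="\t", index=False
            )
            expansion.update(ranking["gene"])
            top = ranking.iloc[0]
            print(
                f"{t1}-{t2}: top gene {top['gene']} "
                f"(min count {top['score']}, total {top['total']})"
            )

    expanded = expand_network(
        glk_net, sorted(expansion), corr, rule, profile, cfg.focus_tissues
    )
    filtered = ppi_filter(expanded, ppi)
    io.write_network(expanded, ROOT / "expanded_network")
    io.write_network(filtered, ROOT / "ppi_filtered_network")
    print(
        f"expanded network: {expanded.number_of_nodes()} genes, "
        f"{expanded.number_of_edges()} edges; "
        f"{filtered.number_of_edges()} edges survive the PPI filter"
    )


if __name__ == "__main__":
    main()
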