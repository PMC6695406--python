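"""End-to-end orchestration: expression -> networks -> tables -> manifest.

``run_pipeline`` executes the full analysis on either real input files or
the built-in synthetic benchmark, writing every network (edge-list TSV,
node TSV, GraphML), the proximity matrix, rankings, edge fractions,
centrality and family tables, and a JSON manifest recording the config,
seed and all logged counts.  Reruns with the same config and seed produce
identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io
from .coexpression import (
    CorrelationMatrix,
    average_by_tissue,
    build_network,
    cross_tissue_correlation,
    select_focal_edges,
)
from .core import (
    ExpressionMatrix,
    FOCAL_CLASSES,
    GeneSetCatalog,
    PipelineConfig,
    PPINetwork,
    SampleDesign,
    TissueProfile,
    XTissueError,
)
from .expansion import (
    EdgeRule,
    expand_network,
    ppi_filter,
    rank_paired_tissue,
    rank_single_tissue,
    tissue_connection_counts,
)
from .metrics import (
    betweenness,
    build_family_network,
    degree_table,
    family_edge_counts,
    family_scores,
)
from .rss import annotate_adme, build_rss_network
from .simulate import glk_default, glk_default_config, simulate_all
from .tissue import (
    annotate_network_tissues,
    assign_tissues,
    cluster_proximity,
    control_fractions,
    first_all_focus_cluster,
    focal_edge_fraction,
    hierarchical_order,
    proximity_total,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline computed."""

    config: PipelineConfig
    profile: TissueProfile
    corr_full: CorrelationMatrix
    focal_network: nx.Graph
    glk_network: nx.Graph
    expanded_network: nx.Graph
    filtered_network: nx.Graph
    rss_network: nx.Graph
    proximity: pd.DataFrame
    tissue_order: list[str]
    fractions: pd.DataFrame
    connection_counts: pd.DataFrame
    paired_rankings: dict[tuple[str, str], pd.DataFrame]
    single_rankings: dict[str, pd.DataFrame]
    family_table: pd.DataFrame
    family_network: nx.Graph
    glk_centrality: pd.DataFrame
    rss_centrality: pd.DataFrame
    rss_degrees: pd.DataFrame
    manifest: dict


def glk_genes_by_tissue(
    net: nx.Graph, assignment: pd.Series, focus_tissues: tuple[str, ...]
) -> dict[str, list[str]]:
    """Focus-tissue -> genes of the focal network assigned to that tissue."""
    out: dict[str, list[str]] = {t: [] for t in focus_tissues}
    for g in sorted(net.nodes):
        t = assignment.get(g)
        if t in out:
            out[t].append(g)
    return out


def run_pipeline(
    config: PipelineConfig,
    expr: ExpressionMatrix,
    design: SampleDesign,
    catalog: GeneSetCatalog,
    ppi: PPINetwork,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full cross-tissue analysis; optionally write a run directory."""
    manifest: dict = {"config": config.to_dict(), "counts": {}}
    counts = manifest["counts"]

    # 1-2. tissue means and cross-tissue correlation
    profile = average_by_tissue(expr, design)
    if config.correlation_scope == "samples":
        sample_profile = TissueProfile(expr.data)
        corr_full = cross_tissue_correlation(
            sample_profile, log_transform=config.log_transform
        )
    else:
        corr_full = cross_tissue_correlation(
            profile, log_transform=config.log_transform
        )

    # 3-4. focal subsetting and edge selection
    focal_classes = set(FOCAL_CLASSES)
    edges = select_focal_edges(
        corr_full, catalog, focal_classes, config.edge_mode, config.edge_value
    )
    focal_net = build_network(edges, catalog)
    counts["n_focal_genes"] = focal_net.number_of_nodes()
    counts["n_focal_edges"] = focal_net.number_of_edges()

    # 5. tissue annotation, proximity, dendrogram ordering
    annotate_network_tissues(focal_net, profile, config.focus_tissues)
    assignment = assign_tissues(profile)
    prox = cluster_proximity(
        focal_net,
        assignment.loc[sorted(focal_net.nodes)],
        tissues=profile.tissues,
    )
    order = hierarchical_order(prox)
    counts["proximity_total"] = proximity_total(prox)
    focus_cluster = first_all_focus_cluster(order, config.focus_tissues)
    if focus_cluster is not None:
        members, height = focus_cluster
        manifest["focus_cluster"] = {
            "members": sorted(members),
            "height": height,
        }

    # GLK subnetwork: focal genes assigned to the focus tissues
    glk_nodes = [
        g
        for g in sorted(focal_net.nodes)
        if focal_net.nodes[g]["tissue"] in config.focus_tissues
    ]
    glk_net = focal_net.subgraph(glk_nodes).copy()
    counts["n_glk_genes"] = glk_net.number_of_nodes()
    counts["n_glk_edges"] = glk_net.number_of_edges()
    by_tissue = glk_genes_by_tissue(focal_net, assignment, config.focus_tissues)
    counts["glk_genes_per_tissue"] = {t: len(g) for t, g in by_tissue.items()}

    # edge-fraction statistic vs control samples
    focal_genes = sorted(
        set(catalog.genes_of_classes(focal_classes)) & set(corr_full.gene_ids)
    )
    k = (
        int(config.edge_value)
        if config.edge_mode == "top_k"
        else counts["n_focal_edges"]
    )
    focal_frac = focal_edge_fraction(
        corr_full, focal_genes, k, profile, config.focus_tissues
    )
    random_pool = sorted(set(corr_full.gene_ids) - set(focal_genes))
    rows = [
        {
            "gene_set": "focal",
            "mean_fraction": focal_frac.fraction,
            "sd": 0.0,
            "n_edges": focal_frac.n_edges,
        }
    ]
    size = min(len(focal_genes), len(random_pool))
    rand = control_fractions(
        corr_full,
        random_pool,
        size,
        k,
        profile,
        config.focus_tissues,
        reps=config.control_reps,
        seed=config.seed,
    )
    rows.append(
        {
            "gene_set": "random",
            "mean_fraction": rand.mean,
            "sd": rand.sd,
            "n_edges": k,
        }
    )
    control_pool = sorted(
        set(catalog.genes_of_classes({"control"})) & set(corr_full.gene_ids)
    )
    if control_pool:
        csize = min(size, len(control_pool))
        ctrl = control_fractions(
            corr_full,
            control_pool,
            csize,
            k,
            profile,
            config.focus_tissues,
            reps=config.control_reps,
            seed=config.seed + 1,
        )
        rows.append(
            {
                "gene_set": "control_class",
                "mean_fraction": ctrl.mean,
                "sd": ctrl.sd,
                "n_edges": k,
            }
        )
    fractions = pd.DataFrame(rows)

    # 6a. connectivity ranking of outside genes + expansion
    rule = EdgeRule(config.expansion_edge_mode, config.expansion_edge_value)
    candidates = sorted(set(corr_full.gene_ids) - set(focal_genes))
    conn = tissue_connection_counts(corr_full, by_tissue, candidates, rule)
    singles = {
        t: rank_single_tissue(conn, t, config.transcriptome_top_m)
        for t in sorted(by_tissue)
    }
    pairs = {}
    expansion_genes: set[str] = set()
    tissues = sorted(by_tissue)
    for i, t1 in enumerate(tissues):
        for t2 in tissues[i + 1 :]:
            ranking = rank_paired_tissue(conn, (t1, t2), config.expansion_top_n)
            pairs[(t1, t2)] = ranking
            expansion_genes.update(ranking["gene"])
    expanded = expand_network(
        glk_net, sorted(expansion_genes), corr_full, rule, profile, config.focus_tissues
    )
    counts["n_expansion_genes"] = len(expansion_genes)
    counts["n_expanded_edges"] = expanded.number_of_edges()

    # 6b. PPI filtering
    filtered = ppi_filter(expanded, ppi)
    counts["n_edges_before_ppi"] = expanded.number_of_edges()
    counts["n_edges_after_ppi"] = filtered.number_of_edges()

    # 6c. ADME annotation and the RSS network
    adme_counts = annotate_adme(filtered, catalog)
    counts["adme_status_counts"] = adme_counts
    rss_net = build_rss_network(filtered)
    counts["n_rss_genes"] = rss_net.number_of_nodes()
    counts["n_rss_edges"] = rss_net.number_of_edges()
    rss_centrality = betweenness(rss_net)
    rss_degrees = degree_table(rss_net, config.degree_report_threshold)

    # 6d. centrality of the PPI-filtered GLK network and family network
    glk_centrality = betweenness(filtered)
    fam_counts, fam_sizes = family_edge_counts(glk_net, catalog)
    fam_table = family_scores(
        fam_counts,
        fam_sizes,
        glk_net.number_of_edges(),
        glk_net.number_of_nodes(),
    )
    fam_net = build_family_network(fam_table, config.family_score_threshold)
    fam_bc = betweenness(fam_net)
    counts["n_family_groups"] = fam_net.number_of_nodes()
    counts["n_family_edges"] = fam_net.number_of_edges()

    result = PipelineResult(
        config=config,
        profile=profile,
        corr_full=corr_full,
        focal_network=focal_net,
        glk_network=glk_net,
        expanded_network=expanded,
        filtered_network=filtered,
        rss_network=rss_net,
        proximity=prox,
        tissue_order=order.tissues,
        fractions=fractions,
        connection_counts=conn,
        paired_rankings=pairs,
        single_rankings=singles,
        family_table=fam_table,
        family_network=fam_net,
        glk_centrality=glk_centrality,
        rss_centrality=rss_centrality,
        rss_degrees=rss_degrees,
        manifest=manifest,
    )
    manifest["tissue_order"] = order.tissues
    if outdir is not None:
        _write_run(result, fam_bc, Path(outdir))
    return result


def _write_run(result: PipelineResult, fam_bc: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_network(result.focal_network, outdir / "focal_network")
    io.write_network(result.glk_network, outdir / "glk_network")
    io.write_network(result.expanded_network, outdir / "expanded_network")
    io.write_network(result.filtered_network, outdir / "ppi_filtered_network")
    io.write_network(result.rss_network, outdir / "rss_network")
    io.write_network(result.family_network, outdir / "family_network")
    result.proximity.to_csv(outdir / "proximity_matrix.csv")
    with open(outdir / "tissue_order.json", "w") as fh:
        json.dump(result.tissue_order, fh, indent=2)
    result.fractions.to_csv(outdir / "edge_fractions.tsv", sep="\t", index=False)
    result.connection_counts.rename_axis("gene").to_csv(
        outdir / "connection_counts.tsv", sep="\t"
    )
    for t, ranking in result.single_rankings.items():
        ranking.to_csv(outdir / f"ranking_single_{t}.tsv", sep="\t", index=False)
    for (t1, t2), ranking in result.paired_rankings.items():
        ranking.to_csv(
            outdir / f"ranking_paired_{t1}_{t2}.tsv", sep="\t", index=False
        )
    result.family_table.to_csv(outdir / "family_scores.tsv", sep="\t", index=False)
    result.glk_centrality.to_csv(outdir / "glk_centrality.tsv", sep="\t")
    result.rss_centrality.to_csv(outdir / "rss_centrality.tsv", sep="\t")
    result.rss_degrees.to_csv(outdir / "rss_degrees.tsv", sep="\t")
    fam_bc.to_csv(outdir / "family_centrality.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def run_simulated(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the pipeline on the glk_default synthetic benchmark."""
    if config is None:
        config = glk_default_config(seed if seed is not None else 0)
    if seed is not None:
        config.seed = seed
    params = glk_default(config.seed)
    expr, design, catalog, ppi, _ = simulate_all(params)
    return run_pipeline(config, expr, design, catalog, ppi, outdir=outdir)
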