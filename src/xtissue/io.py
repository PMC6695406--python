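"""Readers and writers for the pipeline's on-disk formats.

Canonical formats are plain TSV (expression, design, catalog, PPI edge
list, network edge list, node tables) plus GraphML as a faithful mirror of
the network objects.  All readers are deterministic and order-stable:
unless stated otherwise, output rows are sorted by gene identifier.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .core import (
    DEFAULT_TISSUE_GROUP_MAP,
    ExpressionMatrix,
    GeneSetCatalog,
    PipelineConfig,
    PPINetwork,
    SampleDesign,
    XTissueError,
)

log = logging.getLogger(__name__)


def read_expression(
    path: str | Path,
    design_path: str | Path,
    tissue_group_map: dict | None = None,
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read a genes-x-samples TSV plus its sample->tissue design table.

    The expression file has a header row of sample ids and one gene per
    row; the design has columns ``sample_id`` and ``tissue``.  Every sample
    in the matrix must have a design entry.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad) > 0:
            raise XTissueError(
                f"non-numeric expression value at gene {bad.index[0]!r}, "
                f"sample {col!r} in {path}"
            )
    df = df.astype(float).sort_index().rename_axis(None)

    design_df = pd.read_csv(design_path, sep="\t", dtype=str)
    if not {"sample_id", "tissue"}.issubset(design_df.columns):
        raise XTissueError(
            f"design table {design_path} needs columns sample_id, tissue"
        )
    raw = design_df.set_index("sample_id")["tissue"]
    group_map = (
        dict(DEFAULT_TISSUE_GROUP_MAP)
        if tissue_group_map is None
        else dict(tissue_group_map)
    )
    design = SampleDesign(raw_tissue=raw, tissue_group_map=group_map)
    design.require_samples(df.columns)
    return ExpressionMatrix(df), design


def write_expression(
    expr: ExpressionMatrix,
    design: SampleDesign,
    path: str | Path,
    design_path: str | Path,
) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")
    out = design.raw_tissue.rename("tissue").rename_axis("sample_id")
    out.reset_index().to_csv(design_path, sep="\t", index=False)


def read_catalog(path: str | Path) -> GeneSetCatalog:
    """Read a gene -> family/class/ADME-status catalog TSV.

    The ``adme_status`` column is optional and defaults to ``"none"``.
    Duplicate rows must agree on family, class and status; conflicting
    duplicates are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "family", "class"}
    if not required.issubset(df.columns):
        raise XTissueError(f"catalog {path} needs columns {sorted(required)}")
    if "adme_status" not in df.columns:
        df["adme_status"] = "none"
    df["adme_status"] = df["adme_status"].fillna("none")
    df = df.rename(columns={"class": "gene_class"})
    dup = df[df.duplicated(subset="gene", keep=False)]
    if len(dup) > 0:
        conflicting = dup.groupby("gene").nunique()
        bad = conflicting.index[(conflicting > 1).any(axis=1)].tolist()
        if bad:
            raise XTissueError(
                f"genes with conflicting catalog entries: {bad}"
            )
        df = df.drop_duplicates(subset="gene")
    table = (
        df.set_index("gene")[["family", "gene_class", "adme_status"]]
        .sort_index()
    )
    return GeneSetCatalog(table)


def write_catalog(catalog: GeneSetCatalog, path: str | Path) -> None:
    out = catalog.table.rename(columns={"gene_class": "class"})
    out.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a PPI edge list from two-column TSV or SIF.

    SIF lines have the form ``A <relation> B``; TSV lines ``A<TAB>B``.
    Reversed duplicates collapse to one undirected edge; self-loops are
    dropped (count logged).
    """
    pairs: list[tuple[str, str]] = []
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and [f.lower() for f in fields[:2]] in (
                ["source", "target"],
                ["gene1", "gene2"],
            ):
                continue  # optional header
            if len(fields) == 2:
                a, b = fields
            elif len(fields) == 3:  # SIF: source relation target
                a, _, b = fields
            else:
                raise XTissueError(
                    f"malformed PPI line {lineno} in {path}: {line!r}"
                )
            if a == b:
                n_self += 1
                continue
            pairs.append((a, b))
    if n_self:
        log.info("dropped %d self-loop PPI entries from %s", n_self, path)
    return PPINetwork.from_pairs(pairs)


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene1\tgene2\n")
        for a, b in ppi:
            fh.write(f"{a}\t{b}\n")


# -- network serialization ---------------------------------------------------

_EDGE_COLUMNS = ("source", "target", "correlation", "tissue")


def write_network(net: nx.Graph, prefix: str | Path) -> dict[str, Path]:
    """Write a network as edge-list TSV, node-table TSV and GraphML.

    ``prefix`` is extended with ``.edges.tsv``, ``.nodes.tsv`` and
    ``.graphml``.  Returns the mapping of kind -> path.
    """
    prefix = Path(prefix)
    paths = {
        "edges": prefix.with_suffix(".edges.tsv"),
        "nodes": prefix.with_suffix(".nodes.tsv"),
        "graphml": prefix.with_suffix(".graphml"),
    }
    rows = []
    for u, v, attrs in net.edges(data=True):
        a, b = (u, v) if u <= v else (v, u)
        rows.append(
            {
                "source": a,
                "target": b,
                "correlation": attrs.get("correlation", np.nan),
                "tissue": attrs.get("tissue", ""),
            }
        )
    edges = pd.DataFrame(rows, columns=list(_EDGE_COLUMNS))
    edges = edges.sort_values(["source", "target"]).reset_index(drop=True)
    edges.to_csv(paths["edges"], sep="\t", index=False)

    node_rows = []
    for g in sorted(net.nodes):
        row = {"gene": g}
        row.update(net.nodes[g])
        node_rows.append(row)
    pd.DataFrame(node_rows).to_csv(paths["nodes"], sep="\t", index=False)

    clean = nx.Graph()
    for g in sorted(net.nodes):
        clean.add_node(g, **_graphml_safe(net.nodes[g]))
    for u, v, attrs in net.edges(data=True):
        clean.add_edge(u, v, **_graphml_safe(attrs))
    nx.write_graphml(clean, paths["graphml"])
    return paths


def _graphml_safe(attrs: dict) -> dict:
    out = {}
    for k, v in attrs.items():
        if isinstance(v, (bool, np.bool_)):
            v = bool(v)
        elif isinstance(v, (int, np.integer)):
            v = int(v)
        elif isinstance(v, (float, np.floating)):
            v = float(v)
        else:
            v = str(v)
        out[k] = v
    return out


def read_network(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(graphml_path, node_type=str)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
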