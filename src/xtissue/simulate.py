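"""Synthetic tissue-stratified expression, catalogs and PPI networks.

The generator plants the statistical structure the analysis is designed to
detect: tissue-specific co-expression modules concentrated in gut, liver
and kidney for the focal transporter/DME classes, two-tissue "bridge" and
"hub" modules that create cross-tissue connectivity, a coherent control
class standing in for non-olfactory GPCRs, diffusely expressed background
genes, and a PPI network partially concordant with the planted modules.

Expression follows a log-normal model: the value for gene *g* in sample
*s* is ``exp(mu + beta * [tissue(s) in elevated(module(g))] + eps)`` with
``eps ~ N(0, sigma^2)`` i.i.d.  Background genes carry no ``beta`` term.
All outputs are pure functions of ``(params, seed)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    FOCAL_CLASSES,
    GENE_CLASSES,
    GeneSetCatalog,
    PipelineConfig,
    PPINetwork,
    SampleDesign,
    XTissueError,
)


@dataclass(frozen=True)
class ModuleSpec:
    """One planted co-expression module."""

    module_id: str
    n_genes: int
    elevated_tissues: tuple[str, ...]  # 1 or 2 grouped tissue labels
    gene_class: str
    family: str

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise XTissueError("module member counts must be >= 2")
        if not 1 <= len(self.elevated_tissues) <= 2:
            raise XTissueError("modules span 1 or 2 elevated tissues")
        if self.gene_class not in GENE_CLASSES:
            raise XTissueError(f"unknown class {self.gene_class!r}")


@dataclass(frozen=True)
class SimulationParams:
    tissues: tuple[str, ...]
    samples_per_tissue: int
    modules: tuple[ModuleSpec, ...]
    n_background: int
    mu: float = 3.0  # baseline log-mean of normalized counts
    beta: float = 2.5  # log-scale elevation in module tissues
    sigma: float = 0.5  # per-(gene, sample) log-scale noise sd
    ppi_true_fraction: float = 0.8
    ppi_shared_tissue_fraction: float = 0.15
    ppi_noise_fraction: float = 0.001
    adme_core_fraction: float = 0.05
    adme_extended_fraction: float = 0.25
    adme_related_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ppi_true_fraction",
            "ppi_shared_tissue_fraction",
            "ppi_noise_fraction",
            "adme_core_fraction",
            "adme_extended_fraction",
            "adme_related_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise XTissueError(f"{name} must lie in [0, 1]")
        if self.beta <= 0:
            raise XTissueError("tissue effect beta must be > 0")
        if self.sigma < 0:
            raise XTissueError("noise sd sigma must be >= 0")
        for m in self.modules:
            for t in m.elevated_tissues:
                if t not in self.tissues:
                    raise XTissueError(
                        f"module {m.module_id}: tissue {t!r} not simulated"
                    )
        names = [g for m in self.modules for g in module_gene_ids(m)]
        if len(names) != len(set(names)):
            raise XTissueError("gene ids not unique across modules")

    @property
    def gene_ids(self) -> list[str]:
        genes = [g for m in self.modules for g in module_gene_ids(m)]
        genes += background_gene_ids(self.n_background)
        return genes


def module_gene_ids(mod: ModuleSpec) -> list[str]:
    return [f"{mod.family}_{i + 1:03d}" for i in range(mod.n_genes)]


def background_gene_ids(n: int) -> list[str]:
    return [f"BG_{i + 1:04d}" for i in range(n)]


@dataclass
class GroundTruth:
    """Planted assignment backing a simulated dataset."""

    gene_module: dict[str, str | None]
    module_tissues: dict[str, tuple[str, ...]]
    module_class: dict[str, str]
    module_family: dict[str, str]
    ppi_true_edges: set[tuple[str, str]] = field(default_factory=set)

    def genes_of_module(self, module_id: str) -> list[str]:
        return sorted(
            g for g, m in self.gene_module.items() if m == module_id
        )


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, stream)))


def simulate_expression(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SampleDesign, GroundTruth]:
    """Draw a tissue-stratified expression matrix with planted modules."""
    rng = _child_rng(params.seed, 0)
    samples, sample_tissue = [], []
    for t in params.tissues:
        for i in range(params.samples_per_tissue):
            samples.append(f"{t.replace(' ', '_')}_s{i + 1}")
            sample_tissue.append(t)
    sample_tissue = np.asarray(sample_tissue)

    genes = params.gene_ids
    elevated = {}  # gene -> boolean mask over samples
    truth = GroundTruth({}, {}, {}, {})
    for mod in params.modules:
        mask = np.isin(sample_tissue, list(mod.elevated_tissues))
        truth.module_tissues[mod.module_id] = tuple(mod.elevated_tissues)
        truth.module_class[mod.module_id] = mod.gene_class
        truth.module_family[mod.module_id] = mod.family
        for g in module_gene_ids(mod):
            elevated[g] = mask
            truth.gene_module[g] = mod.module_id
    for g in background_gene_ids(params.n_background):
        truth.gene_module[g] = None

    n_g, n_s = len(genes), len(samples)
    log_values = np.full((n_g, n_s), params.mu)
    for i, g in enumerate(genes):
        if g in elevated:
            log_values[i, elevated[g]] += params.beta
    log_values += rng.normal(0.0, params.sigma, size=(n_g, n_s))
    df = pd.DataFrame(np.exp(log_values), index=genes, columns=samples)
    df = df.sort_index()

    design = SampleDesign(
        raw_tissue=pd.Series(sample_tissue, index=samples, name="tissue"),
        tissue_group_map={},
    )
    return ExpressionMatrix(df), design, truth


def simulate_catalog(params: SimulationParams) -> GeneSetCatalog:
    """Build the gene -> family/class/ADME-status catalog for a scenario.

    Module genes carry their module's class and family; background genes
    are class ``other`` (family ``BG``).  ADME statuses are seeded draws:
    focal-class genes become ``core``/``extended`` with the stated
    fractions, and genes of non-focal, non-control modules become
    ``related`` (emulating the curated "related" list, which is mostly
    non-transporter genes found near the network).
    """
    rng = _child_rng(params.seed, 1)
    rows = []
    for mod in params.modules:
        for g in module_gene_ids(mod):
            u = rng.random()
            if mod.gene_class in FOCAL_CLASSES:
                if u < params.adme_core_fraction:
                    status = "core"
                elif u < params.adme_core_fraction + params.adme_extended_fraction:
                    status = "extended"
                else:
                    status = "none"
            elif mod.gene_class == "other":
                status = "related" if u < params.adme_related_fraction else "none"
            else:
                status = "none"
            rows.append((g, mod.family, mod.gene_class, status))
    for g in background_gene_ids(params.n_background):
        rows.append((g, "BG", "other", "none"))
    table = pd.DataFrame(
        rows, columns=["gene", "family", "gene_class", "adme_status"]
    ).set_index("gene").sort_index()
    return GeneSetCatalog(table)


def simulate_ppi(truth: GroundTruth, params: SimulationParams) -> PPINetwork:
    """Draw a PPI network partially concordant with the planted modules.

    Within-module pairs are true edges with probability
    ``ppi_true_fraction``; pairs from different modules sharing an elevated
    tissue with ``ppi_shared_tissue_fraction``; all remaining pairs with
    ``ppi_noise_fraction``.
    """
    rng = _child_rng(params.seed, 2)
    pairs: set[tuple[str, str]] = set()
    module_ids = sorted(truth.module_tissues)
    members = {m: truth.genes_of_module(m) for m in module_ids}

    special: set[tuple[str, str]] = set()
    for m in module_ids:
        for a, b in itertools.combinations(members[m], 2):
            special.add((a, b))
            if rng.random() < params.ppi_true_fraction:
                pairs.add((a, b))
    truth.ppi_true_edges = set(pairs)

    for m1, m2 in itertools.combinations(module_ids, 2):
        if set(truth.module_tissues[m1]) & set(truth.module_tissues[m2]):
            for a in members[m1]:
                for b in members[m2]:
                    key = (a, b) if a <= b else (b, a)
                    special.add(key)
                    if rng.random() < params.ppi_shared_tissue_fraction:
                        pairs.add(key)

    if params.ppi_noise_fraction > 0:
        genes = sorted(truth.gene_module)
        n = len(genes)
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < params.ppi_noise_fraction
        for i, j in zip(iu[keep], ju[keep]):
            key = (genes[i], genes[j])
            if key not in special:
                pairs.add(key)
    return PPINetwork.from_pairs(pairs)


def simulate_all(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SampleDesign, GeneSetCatalog, PPINetwork, GroundTruth]:
    expr, design, truth = simulate_expression(params)
    catalog = simulate_catalog(params)
    ppi = simulate_ppi(truth, params)
    return expr, design, catalog, ppi, truth


# -- named scenarios ---------------------------------------------------------

GLK_TISSUES = (
    "gut",
    "liver",
    "kidney",
    "brain",
    "lung",
    "heart",
    "muscle",
    "skin",
    "testis",
    "pancreas",
    "spleen",
    "thyroid",
)

#: planted cross-tissue hub module (non-focal, elevated in liver + kidney)
HUB_MODULE_ID = "hub_liver_kidney"


def glk_default(seed: int = 0) -> SimulationParams:
    """The default gut-liver-kidney benchmark scenario.

    ~1,200 genes over 12 tissues x 4 samples: six single-tissue focal
    modules concentrated in gut/liver/kidney, three two-tissue focal bridge
    modules within GLK, one non-GLK focal module (brain), one non-focal
    module (testis), one coherent GPCR-like control module (brain), one
    non-focal liver+kidney hub module, and diffuse background genes.
    """
    modules = (
        ModuleSpec("slc22_gut", 30, ("gut",), "SLC", "SLC22"),
        ModuleSpec("slc25_liver", 30, ("liver",), "SLC", "SLC25"),
        ModuleSpec("slc35_kidney", 30, ("kidney",), "SLC", "SLC35"),
        ModuleSpec("cyp_liver", 25, ("liver",), "DME_phase1", "CYP"),
        ModuleSpec("ugt_gut", 25, ("gut",), "DME_phase2", "UGT"),
        ModuleSpec("abcc_kidney", 20, ("kidney",), "ABC", "ABCC"),
        ModuleSpec("slco_gut_liver", 12, ("gut", "liver"), "SLC", "SLCO"),
        ModuleSpec("abcg_gut_kidney", 12, ("gut", "kidney"), "ABC", "ABCG"),
        ModuleSpec("sult_liver_kidney", 12, ("liver", "kidney"), "DME_phase2", "SULT"),
        ModuleSpec("slc6_brain", 30, ("brain",), "SLC", "SLC6"),
        ModuleSpec("tex_testis", 25, ("testis",), "other", "TEX"),
        ModuleSpec("gpcr_control", 240, ("brain",), "control", "GPCR"),
        ModuleSpec(HUB_MODULE_ID, 12, ("liver", "kidney"), "other", "LKHUB"),
    )
    return SimulationParams(
        tissues=GLK_TISSUES,
        samples_per_tissue=4,
        modules=modules,
        n_background=707,
        seed=seed,
    )


def glk_default_config(seed: int = 0) -> PipelineConfig:
    """Pipeline configuration matched to the glk_default problem size.

    The focal universe has ~226 genes (~25k unordered pairs); an edge
    budget of 3,000 keeps the selected edges inside the planted
    strong-correlation tier, playing the role the 10,000-edge cut plays
    for the full-scale 690-gene study.
    """
    return PipelineConfig(edge_mode="top_k", edge_value=3000, seed=seed)
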