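"""Core domain types shared by every stage of the pipeline.

Expression data are held as pandas objects (genes x samples / genes x
tissues); co-expression and PPI networks are :class:`networkx.Graph`
instances with documented node/edge attribute conventions:

* co-expression network nodes carry ``gene_class``, ``family``,
  ``adme_status`` and (after annotation) ``tissue``; edges carry
  ``correlation``, ``tissue`` (focus label or ``"other"``) and
  ``tissue_argmax`` (the unrestricted argmax tissue).
* PPI networks are plain unordered gene-pair sets (:class:`PPINetwork`).

Gene identifiers are opaque, case-sensitive, HGNC-symbol-like strings; no
identifier mapping is performed anywhere in the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

GENE_CLASSES = frozenset(
    {"SLC", "ABC", "DME_phase1", "DME_phase2", "control", "other"}
)
#: gene classes counted as "focal" (transporter / DME) in the study design
FOCAL_CLASSES = frozenset({"SLC", "ABC", "DME_phase1", "DME_phase2"})
ADME_STATUSES = frozenset({"core", "extended", "related", "none"})

#: raw tissue labels folded into the grouped "gut" label by default
DEFAULT_TISSUE_GROUP_MAP: Mapping[str, str] = {
    "small intestine": "gut",
    "duodenum": "gut",
}


class XTissueError(ValueError):
    """Base error for invariant violations and malformed inputs."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative normalized counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise XTissueError(f"duplicate gene identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise XTissueError(f"duplicate sample identifiers: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise XTissueError(
                f"expression matrix must be at least 2x2, got {df.shape}"
            )
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise XTissueError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise XTissueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise XTissueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class SampleDesign:
    """sample -> tissue assignment, with raw labels folded into groups.

    ``tissue`` holds the grouped labels used by every downstream stage;
    ``raw_tissue`` keeps the labels as given in the design table.
    """

    raw_tissue: pd.Series
    tissue_group_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_GROUP_MAP)
    )

    def __post_init__(self) -> None:
        if self.raw_tissue.index.duplicated().any():
            raise XTissueError("duplicate sample identifiers in design")

    @property
    def tissue(self) -> pd.Series:
        mapped = self.raw_tissue.map(
            lambda t: self.tissue_group_map.get(t, t)
        )
        mapped.name = "tissue"
        return mapped

    @property
    def tissues(self) -> list[str]:
        """Distinct grouped tissue labels, sorted."""
        return sorted(self.tissue.unique())

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.raw_tissue.index]
        if missing:
            raise XTissueError(
                f"samples missing from design table: {missing}"
            )


@dataclass(frozen=True)
class TissueProfile:
    """Genes x tissues matrix of per-tissue mean expression."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise XTissueError("tissue profile contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class GeneSetCatalog:
    """gene -> (family, class, ADME status) annotation table.

    Each gene maps to exactly one family and one class; ``adme_status``
    defaults to ``"none"``.
    """

    table: pd.DataFrame  # index: gene; columns: family, gene_class, adme_status

    def __post_init__(self) -> None:
        t = self.table
        required = {"family", "gene_class", "adme_status"}
        if not required.issubset(t.columns):
            raise XTissueError(
                f"catalog table needs columns {sorted(required)}"
            )
        if t.index.duplicated().any():
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise XTissueError(f"duplicate genes in catalog: {dups}")
        bad_class = set(t["gene_class"]) - GENE_CLASSES
        if bad_class:
            raise XTissueError(f"unknown gene classes: {sorted(bad_class)}")
        bad_status = set(t["adme_status"]) - ADME_STATUSES
        if bad_status:
            raise XTissueError(f"unknown ADME statuses: {sorted(bad_status)}")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def genes_of_classes(self, classes: Iterable[str]) -> list[str]:
        classes = set(classes)
        unknown = classes - GENE_CLASSES
        if unknown:
            raise XTissueError(f"unknown gene classes: {sorted(unknown)}")
        mask = self.table["gene_class"].isin(classes)
        return sorted(self.table.index[mask])

    def genes_of_status(self, statuses: Iterable[str]) -> list[str]:
        mask = self.table["adme_status"].isin(set(statuses))
        return sorted(self.table.index[mask])

    def family_of(self, gene: str) -> str:
        return self.table.at[gene, "family"]

    def class_of(self, gene: str) -> str:
        return self.table.at[gene, "gene_class"]

    def status_of(self, gene: str) -> str:
        if gene in self.table.index:
            return self.table.at[gene, "adme_status"]
        return "none"


def _canon_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PPINetwork:
    """Undirected protein-protein interaction edge set (no self-loops)."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PPINetwork":
        canon = set()
        for a, b in pairs:
            if a == b:
                continue
            canon.add(_canon_pair(a, b))
        return cls(frozenset(canon))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return _canon_pair(a, b) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.pairs))


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis, with study defaults.

    ``edge_mode``/``edge_value`` select either the top-k rule (k = 10,000
    in the full-scale study) or a correlation floor (r > 0.59, the
    equivalent cutoff on the original data).  ``expansion_edge_mode``
    controls the adjacency criterion used genome-wide when counting
    candidate connections and expanding the network (threshold by default).
    """

    edge_mode: str = "top_k"  # "top_k" | "threshold"
    edge_value: float = 10_000
    correlation_scope: str = "tissue_means"  # "tissue_means" | "samples"
    log_transform: bool = False
    focus_tissues: tuple[str, ...] = ("gut", "liver", "kidney")
    tissue_group_map: dict = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_GROUP_MAP)
    )
    expansion_edge_mode: str = "threshold"
    expansion_edge_value: float = 0.59
    expansion_top_n: int = 20
    transcriptome_top_m: int = 100
    control_reps: int = 10
    family_score_threshold: float = 2.0
    degree_report_threshold: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.edge_mode not in ("top_k", "threshold"):
            raise XTissueError(f"unknown edge mode {self.edge_mode!r}")
        if self.edge_mode == "top_k" and int(self.edge_value) <= 0:
            raise XTissueError("top_k edge count must be a positive integer")
        if self.edge_mode == "threshold" and not (0 < self.edge_value < 1):
            raise XTissueError("correlation threshold must lie in (0, 1)")
        for name in ("expansion_top_n", "transcriptome_top_m", "control_reps"):
            if int(getattr(self, name)) <= 0:
                raise XTissueError(f"{name} must be a positive integer")
        if self.correlation_scope not in ("tissue_means", "samples"):
            raise XTissueError(
                f"unknown correlation scope {self.correlation_scope!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["focus_tissues"] = list(self.focus_tissues)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "focus_tissues" in kwargs:
            kwargs["focus_tissues"] = tuple(kwargs["focus_tissues"])
        return cls(**kwargs)
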