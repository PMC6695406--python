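# xtissue

Cross-tissue co-expression network analysis of SLC/ABC transporter and
drug-metabolizing-enzyme (DME) genes, centered on the gut-liver-kidney
(GLK) axis.

## The scientific problem

Multi-specific "drug" transporters (SLC and ABC superfamilies) and Phase
1/2 drug-metabolizing enzymes move and modify not just pharmaceuticals
but bile acids, uric acid, gut-microbiome products, uremic solutes and
many other endogenous small molecules. The Remote Sensing and Signaling
Hypothesis proposes that these ADME genes form an inter-organ
communication system. `xtissue` operationalizes one way to map that
system: if two genes are expressed in similar sets of tissues, they are
candidates for acting in shared or complementary pathways — so a
co-expression network built *across* tissues, restricted to transporter
and DME genes and labeled by tissue of highest expression, exposes which
organs share dense blocks of these genes and which outside genes (e.g.,
nuclear receptors) tie the organ clusters together.

The pipeline, stage by stage:

1. **Tissue profile.** Average normalized counts per (gene, tissue) over
   the sample design; Pearson's r between gene profiles across tissues.
2. **Focal network.** Restrict to focal classes (SLC, ABC, DME Phase
   1/2) and keep the top-k correlated pairs (k = 10,000 in the original
   full-scale setting; equivalently r > 0.59 as a threshold mode).
3. **Tissue labels.** Gene → argmax tissue of its mean expression; edge →
   argmax of the two endpoints' mean profile. Counting edges between
   tissue assignments gives a tissue x tissue proximity matrix; average-
   linkage clustering (distance = 1 − Pearson r between rows) orders its
   heatmap. The fraction of top edges labeled gut/liver/kidney is
   compared against size-matched random samples and a GPCR-like control
   class (mean ± sd over 10 draws).
4. **Expansion.** Every outside gene is scored by its number of
   co-expression connections to gut-, liver- and kidney-assigned focal
   genes; for each tissue pair, genes are ranked by
   `min(count_t1, count_t2)` and the top 20 per pair join the network.
5. **PPI filter.** Only edges also present in a protein-protein
   interaction network are kept (nodes retained), prioritizing likely
   physical interactions.
6. **RSS network and rankings.** Curated ADME genes (core / extended /
   related) plus their first neighbors in the PPI-filtered network form
   the remote sensing and signaling (RSS) network. Normalized
   betweenness centrality and degree tables rank genes; gene families
   (SLC/ABC families, DME phases pooled) form a family network whose
   edges are kept when the upper-tail hypergeometric score
   −log10 P(X ≥ x) exceeds 2 (p < 0.01).

A synthetic-data module generates expression matrices, catalogs and PPI
networks with planted tissue modules so the entire analysis runs with no
downloads.

## Worked example

```sh
xtissue run --simulate --seed 0 --out run0
```

prints (abridged):

```
focal network: 215 genes / 3000 edges; GLK edges 5962 -> 1493 after PPI; RSS network: 184 genes / 1446 edges
```

i.e. on the synthetic benchmark the focal transporter/DME network keeps
3,000 edges over 215 genes; after expansion, 1,493 of 5,962 edges are
also PPI-supported; and the ADME-centered RSS network spans 184 genes.
The same run as a stage-by-stage narrative lives under `analysis/`
(`01_simulate_dataset.py` … `05_validation_overlap.py`); running them in
order reports, among other things:

```
first cluster containing all focus tissues: ['gut', 'kidney', 'liver'] (merge height 1.088)
GLK edge fraction: focal 0.897 | random 0.069 +/- 0.028 | GPCR-like control 0.000 +/- 0.000
kidney-liver: top gene LKHUB_002 (min count 54, total 113)
HNF4A: 85/108 associated genes supported (78.7%)
```

— gut, liver and kidney form the tightest tissue cluster in the
dendrogram; ~90% of the focal set's strongest edges map to GLK versus
~7% for random size-matched gene sets; the planted liver+kidney hub
genes top the paired-tissue ranking; and the validation-overlap
statistic reproduces the published knockout/ChIP support percentages
from their evidence counts.

The validation statistic is also available directly:

```sh
xtissue overlap --associated 108 --supported 85   # -> 85/108 = 78.7%
```

## Layout

- `src/xtissue/` — the library: `core` (types), `io`, `simulate`,
  `coexpression`, `tissue`, `expansion`, `metrics`, `rss`, `pipeline`,
  `cli`.
- `analysis/` — numbered narrative drivers writing tables under
  `results/`.
- `docs/methods.md` — model, parameters, numerical choices and known
  limitations.
- `tests/` — unit, property and acceptance tests (independent
  brute-force oracles in `tests/_oracles.py`).
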