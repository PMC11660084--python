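# hypoxnet

Analysis pipeline for long-term hypoxia transcriptomics in stored fruit.

Commercial apple storage keeps fruit for months under controlled
atmosphere (CA, ~2% O₂), often combined with the ethylene-perception
inhibitor 1-MCP. The fruit transcriptome responds along two axes: an
early, oxygen-sensed response routed through the N-degron pathway
(ERF VII transcription factors stabilized under hypoxia bind HRPE
promoter elements), and a late response that additionally requires
intact ethylene signaling. `hypoxnet` implements the complete analysis
that separates these responses from a treatment × time RNA-seq count
matrix, for computational biologists studying postharvest or hypoxia
biology:

- **Normalization & differential expression** — median-of-ratios size
  factors `s_j = median_g k_{gj} / (∏_j k_{gj})^{1/m}`; a simplified
  negative-binomial Wald test on group means with delta-method standard
  errors from `Var(K) = μ + αμ²`, genes-pooled moment dispersion, and
  Bonferroni control; up-regulation call log₂FC > 1 and p_adj < 0.05.
- **Contrast-set logic** — the hypoxia-upregulated set (up in CA or
  MCPCA versus *every* normoxic treatment), CA-only / MCPCA-only
  exclusive subsets, and per-timepoint "n-degron" (up in CA ∧ MCPCA vs
  MCP) and "ethylene" (up in CA vs MCP ∧ vs MCPCA) sets.
- **Regulatory-network inference** — GENIE3-style random-forest
  importances (1000 trees, `max_features = sqrt`), out-of-bag r² per
  target, top-5 TFs per target, hypoxia subgraph with a degree-10 TF
  filter, and a TF-role classifier labelling a TF "ethylene-mediated"
  when its target counts fall strictly above the scaled diagonal
  `y = (y_max/x_max)·x`.
- **Motif annotation** — exact IUPAC consensus scanning of 1000-bp
  upstream windows for the HRPE (`GCCVCYGGTTTY`, both strands), CDS
  translation, and the N-terminal `MCGGAI/V` degron census.
- **Enrichment** — hypergeometric over-representation with
  Benjamini–Hochberg adjustment against any term → gene map.
- **Synthetic data** — a negative-binomial simulator of the seven
  treatment groups (PreTreat, A1, A10, A20, MCP, CA, MCPCA) over a
  monthly storage time course, with planted response classes,
  TF → target couplings, and motif-bearing sequences, so every stage is
  testable offline with known ground truth.

## Worked example

```python
import hypoxnet as hx
from hypoxnet.de import run_timepoint_contrasts

cfg = hx.SimConfig(seed=1)                       # ~2000 genes, 102 samples
counts, metadata, truth = hx.simulate_counts(cfg)
expressed = hx.drop_all_zero_genes(counts)
norm = hx.normalize(expressed, hx.estimate_size_factors(expressed))
timed = run_timepoint_contrasts(
    norm, metadata, [("CA", "MCP"), ("MCPCA", "MCP"), ("CA", "MCPCA")],
    cfg.longterm_months,
)
tsets = hx.build_time_resolved_sets(timed, cfg.longterm_months)
print(tsets.sizes().to_string(index=False))
```

prints

```
 timepoint  n_degron  ethylene
         2       299         0
         4       209         0
         5       164         0
         6       155        11
         7       152        66
         8       154       121
         9       152       152
```

The "n-degron" curve (genes up under hypoxia with *and* without
ethylene perception) starts high and decays as the transiently induced
genes fade, while the "ethylene" curve (genes needing intact ethylene
perception) is empty at two months and rises steeply late in storage —
the two-phase structure of the long-term hypoxia response. The planted
sustained hypoxia class is recovered in every month's n-degron set with
≥ 0.96 sensitivity under the default configuration.

More narrative scripts live in `examples/` (one per capability:
simulation, DE, set logic, networks, motifs, enrichment). A thin CLI
mirrors the stages: `hypoxnet simulate|de|grn|motif|enrich|run-all`.

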