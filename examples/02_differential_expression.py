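"""Median-of-ratios normalization and one NB Wald contrast.

Contrasts the controlled-atmosphere treatment (hypoxia) against 1-MCP-
treated air-stored fruit (normoxia, no ethylene perception), pooling all
timepoints as in the treatment-level analyses.
"""

import hypoxnet as hx
from hypoxnet.de import samples_of

cfg = hx.SimConfig(n_genes=500, n_tfs=20, seed=1)
counts, metadata, truth = hx.simulate_counts(cfg)
expressed = hx.drop_all_zero_genes(counts)
size_factors = hx.estimate_size_factors(expressed)
norm = hx.normalize(expressed, size_factors)

table = hx.wald_contrast_table(
    norm, samples_of(metadata, "CA"), samples_of(metadata, "MCP"),
    contrast=("CA", "MCP"),
)
up = hx.call_upregulated(table)  # log2FC > 1 and Bonferroni p < 0.05

print(f"size factors: min {size_factors.min():.3f}, max {size_factors.max():.3f}")
print(f"pooled NB dispersion for this contrast: {table.attrs['dispersion']:.4f}")
print(f"{len(up)} genes called up in CA vs MCP (of {len(table)})")
planted = truth.genes_of_class("ndegron_sustained") | truth.genes_of_class(
    "ndegron_transient"
)
print(f"  of which {len(up & planted)} are planted hypoxia-class genes "
      f"({len(planted)} planted)")
print(table.sort_values("padj").head(5).round(4))
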