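"""Generate a synthetic postharvest storage study.

Builds a counts matrix under the 7-treatment design (baseline, three air
temperatures, 1-MCP, controlled atmosphere, 1-MCP + CA), with planted
hypoxia-response gene classes, TF->target couplings, and promoter/CDS
sequences carrying the HRPE and N-degron motifs.
"""

import hypoxnet as hx

cfg = hx.SimConfig(n_genes=500, n_tfs=20, seed=1)
counts, metadata, truth = hx.simulate_counts(cfg)
seqs = hx.simulate_sequences(truth, seed=1)

print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(metadata.groupby("treatment").size().rename("samples"))
print("\nplanted gene classes:")
for cls in sorted(set(truth.gene_class.values())):
    print(f"  {cls:20s} {len(truth.genes_of_class(cls))}")
print(f"\nplanted TF->target edges: {len(truth.planted_edges)}")
print(f"promoters with a planted HRPE: {len(truth.motif_genes)}")
print(f"TFs with an N-degron CDS: {len(truth.degron_tfs)}")
# Each class follows one of the storage-response archetypes: sustained or
# transient hypoxia induction (CA+MCPCA), a late ethylene-dependent rise
# (CA only), or a maturation response in the air treatments.
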