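"""Contrast-set classification of the hypoxia response.

Builds the hypoxia-upregulated set (up under CA or MCPCA versus every
normoxic treatment), its CA-only / MCPCA-only exclusive subsets, and the
per-timepoint "n-degron" and "ethylene" sets whose sizes over storage
time separate the early oxygen-sensing response from the late
ethylene-dependent response.
"""

import hypoxnet as hx
from hypoxnet.de import run_pooled_contrasts, run_timepoint_contrasts
from hypoxnet.pipeline import _pooled_pairs

cfg = hx.SimConfig(seed=1)
counts, metadata, truth = hx.simulate_counts(cfg)
expressed = hx.drop_all_zero_genes(counts)
norm = hx.normalize(expressed, hx.estimate_size_factors(expressed))

pooled = run_pooled_contrasts(norm, metadata, _pooled_pairs())
sets_ = hx.build_hypoxia_sets(pooled)
print(f"hypoxia-upregulated genes: {len(sets_.hypoxia_all)}")
print(f"  CA-only subset:    {len(sets_.ca_only)} (ethylene-dependent)")
print(f"  MCPCA-only subset: {len(sets_.mcpca_only)}")

timed = run_timepoint_contrasts(
    norm, metadata, [("CA", "MCP"), ("MCPCA", "MCP"), ("CA", "MCPCA")],
    cfg.longterm_months,
)
tsets = hx.build_time_resolved_sets(timed, cfg.longterm_months)
print("\nset sizes by month in storage (n-degron falls, ethylene rises):")
print(tsets.sizes().to_string(index=False))
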