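"""Hypergeometric over-representation of a recovered gene set.

Tests the hypoxia-upregulated set against the (known) simulator classes:
the sustained/transient hypoxia classes should enrich massively; the
maturation class should not.
"""

import hypoxnet as hx
from hypoxnet.de import run_pooled_contrasts
from hypoxnet.pipeline import _pooled_pairs

cfg = hx.SimConfig(n_genes=800, n_tfs=20, seed=1)
counts, metadata, truth = hx.simulate_counts(cfg)
expressed = hx.drop_all_zero_genes(counts)
norm = hx.normalize(expressed, hx.estimate_size_factors(expressed))

pooled = run_pooled_contrasts(norm, metadata, _pooled_pairs())
selected = hx.hypoxia_upregulated_set(pooled) & set(norm.index)
universe = set(norm.index)
term_map = {
    f"class:{c}": truth.genes_of_class(c) & universe
    for c in ("ndegron_sustained", "ndegron_transient", "ethylene_late",
              "maturation")
}
result = hx.enrich(selected, term_map, universe)
print(f"selected {len(selected)} hypoxia-upregulated genes "
      f"of {len(universe)} expressed")
print(result.to_string(index=False))
# small p for the planted hypoxia classes = the set logic recovered the
# planted biology; maturation stays at p ~ 1.
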