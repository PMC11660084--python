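"""Random-forest regulatory network and TF-role classification.

Fits a GENIE3-style forest per target gene, keeps the top-5 TFs per
target, extracts the hypoxia subgraph, and labels each retained TF as a
"standard" or "ethylene-mediated" hypoxia regulator by where its target
counts fall relative to the scaled diagonal y = (y_max/x_max) x.
Kept deliberately small here (fewer genes and trees) so it runs in
seconds; defaults are n_trees=1000.
"""

import hypoxnet as hx

cfg = hx.SimConfig(n_genes=400, n_tfs=20, targets_per_tf=4, seed=1)
counts, metadata, truth = hx.simulate_counts(cfg)
expressed = hx.drop_all_zero_genes(counts)
norm = hx.normalize(expressed, hx.estimate_size_factors(expressed))

filtered = hx.filter_network_genes(norm)            # >=3 in >=10 samples
tfs = hx.filter_expressed_tfs(expressed, truth.tf_ids)
targets = sorted({t for _, t in truth.planted_edges})
net = hx.infer_network(filtered, tfs, targets=targets, n_trees=200, seed=1)
top = hx.threshold_top_k(net, k=5)

kept = set(zip(top.edges["tf"], top.edges["target"]))
recovered = sum(e in kept for e in truth.planted_edges)
print(f"planted edges recovered in the top-5 network: "
      f"{recovered}/{len(truth.planted_edges)}")
print(f"median out-of-bag r2 over targets: {net.r2.median():.3f}")

# role classification against a toy hypoxia set
hypoxia = set(targets)
ethylene_marked = set(targets[: len(targets) // 5])
sub = hx.extract_hypoxia_subgraph(top, hypoxia, min_degree=2)
roles = hx.classify_network_tfs(sub, hypoxia, ethylene_marked)
print(roles.sort_values(["label", "x"], ascending=[True, False]).head(8).to_string(index=False))
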