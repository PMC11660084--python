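import numpy as np
import pandas as pd
import pytest

import hypoxnet as hx


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated study reused across tests."""
    cfg = hx.SimConfig(n_genes=300, n_tfs=15, targets_per_tf=3, seed=11)
    counts, meta, truth = hx.simulate_counts(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    _, counts, meta, _ = small_sim
    expressed = hx.drop_all_zero_genes(counts)
    return hx.normalize(expressed, hx.estimate_size_factors(expressed)), meta


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (used by the recovery suites)."""
    cfg = hx.SimConfig(seed=1)
    counts, meta, truth = hx.simulate_counts(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def default_time_sets(default_sim):
    cfg, counts, meta, truth = default_sim
    expressed = hx.drop_all_zero_genes(counts)
    norm = hx.normalize(expressed, hx.estimate_size_factors(expressed))
    from hypoxnet.de import run_timepoint_contrasts

    timed = run_timepoint_contrasts(
        norm, meta, [("CA", "MCP"), ("MCPCA", "MCP"), ("CA", "MCPCA")],
        cfg.longterm_months,
    )
    return cfg, truth, hx.build_time_resolved_sets(timed, cfg.longterm_months)


def make_de_table(genes, up=(), lfc_up=2.0, padj_up=1e-4):
    """A DE table where ``up`` genes pass the joint up-regulation call."""
    up = set(up)
    lfc = np.array([lfc_up if g in up else 0.0 for g in genes])
    padj = np.array([padj_up if g in up else 1.0 for g in genes])
    table = pd.DataFrame(
        {"log2fc": lfc, "se": 0.1, "p": padj, "padj": padj},
        index=pd.Index(genes, name="gene"),
    )
    return table


@pytest.fixture
def de_table_factory():
    return make_de_table
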