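"""Simulator contracts: design layout, NB moments, determinism, sequences."""

import numpy as np
import pandas as pd
import pytest

import hypoxnet as hx
from hypoxnet.motifs import HRPE, scan_motif, translate_cds


class TestDesign:
    def test_default_design_has_all_treatments_and_replicates(self):
        meta = hx.simulate_design(hx.SimConfig())
        assert set(meta["treatment"]) == set(hx.TREATMENTS)
        cell_sizes = meta.groupby(["treatment", "timepoint"]).size()
        assert (cell_sizes == 3).all()

    def test_longterm_treatments_contribute_21_samples_each(self):
        meta = hx.simulate_design(hx.SimConfig(longterm_months=(2, 4, 5, 6, 7, 8, 9)))
        for treatment in ("MCP", "CA", "MCPCA"):
            assert (meta["treatment"] == treatment).sum() == 21

    def test_pretreat_single_timepoint_zero(self):
        meta = hx.simulate_design(hx.SimConfig())
        pre = meta[meta["treatment"] == "PreTreat"]
        assert set(pre["timepoint"]) == {0.0}

    def test_single_replicate(self):
        meta = hx.simulate_design(hx.SimConfig(n_reps=1))
        assert meta.groupby(["treatment", "timepoint"]).size().eq(1).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"longterm_months": ()},
            {"shortterm_months": (3, 2)},
            {"dispersion": -0.1},
            {"n_tfs": 2000},
            {"class_fractions": {"null": 1.0}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hx.SimConfig(**kwargs)


class TestCounts:
    def test_same_seed_identical_output(self):
        cfg = hx.SimConfig(n_genes=120, n_tfs=8, targets_per_tf=2, seed=5)
        c1, m1, t1 = hx.simulate_counts(cfg)
        c2, m2, t2 = hx.simulate_counts(cfg)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(m1, m2)
        assert t1.planted_edges == t2.planted_edges
        assert t1.gene_class == t2.gene_class

    def test_every_gene_has_one_class_and_edges_from_tfs(self, small_sim):
        cfg, counts, _, truth = small_sim
        assert set(truth.gene_class) == set(counts.index)
        assert set(truth.gene_class.values()) <= set(hx.simulate.GENE_CLASSES)
        tfs = set(truth.tf_ids)
        assert all(tf in tfs for tf, _ in truth.planted_edges)

    def test_nb_marginal_moments_of_null_genes(self):
        # var = mu + alpha mu^2 within one design cell, across many replicates
        cfg = hx.SimConfig(
            n_genes=200, n_tfs=8, targets_per_tf=0, n_reps=60,
            class_fractions={"null": 1.0, "ndegron_transient": 0.0,
                             "ndegron_sustained": 0.0, "ethylene_late": 0.0,
                             "maturation": 0.0},
            edge_strength=0.0, dispersion=0.1, seed=2,
        )
        counts, meta, _ = hx.simulate_counts(cfg)
        cell = meta.loc[meta.sample_id.str.startswith("CA_t2_"), "sample_id"]
        block = counts[cell.tolist()]
        mu = block.mean(axis=1)
        var = block.var(axis=1, ddof=1)
        expected = mu + cfg.dispersion * mu**2
        ratio = var / expected
        assert 0.8 < ratio.median() < 1.2

    def test_zero_dispersion_is_poisson(self):
        cfg = hx.SimConfig(
            n_genes=100, n_tfs=5, targets_per_tf=0, n_reps=80,
            class_fractions={"null": 1.0, "ndegron_transient": 0.0,
                             "ndegron_sustained": 0.0, "ethylene_late": 0.0,
                             "maturation": 0.0},
            edge_strength=0.0, dispersion=0.0, seed=3,
        )
        counts, meta, _ = hx.simulate_counts(cfg)
        cell = meta.loc[meta.sample_id.str.startswith("MCP_t2_"), "sample_id"]
        block = counts[cell.tolist()]
        ratio = block.var(axis=1, ddof=1) / block.mean(axis=1)
        assert 0.8 < ratio.median() < 1.2

    def test_null_model_gives_nominal_false_call_rate(self):
        # effect 0 + coupling 0: genes exchangeable, raw p uniform-ish
        cfg = hx.SimConfig(n_genes=1000, n_tfs=5, targets_per_tf=0,
                           effect_log2fc=0.0, edge_strength=0.0, seed=4)
        counts, meta, _ = hx.simulate_counts(cfg)
        expressed = hx.drop_all_zero_genes(counts)
        norm = hx.normalize(expressed, hx.estimate_size_factors(expressed))
        from hypoxnet.de import samples_of, wald_contrast_table
        table = hx.wald_contrast_table(
            norm, samples_of(meta, "CA"), samples_of(meta, "MCP"),
        )
        frac = (table["p"] < 0.05).mean()
        assert 0.01 < frac < 0.12
        assert len(hx.call_upregulated(table)) == 0

    def test_induction_profiles(self):
        cfg = hx.SimConfig()
        t0, t1 = cfg.longterm_months[0], cfg.longterm_months[-1]
        assert hx.class_log2_induction("ndegron_sustained", "CA", t1, cfg) == 2.0
        assert hx.class_log2_induction("ndegron_transient", "CA", t0, cfg) == 2.0
        assert hx.class_log2_induction("ndegron_transient", "MCPCA", t1, cfg) == 0.0
        assert hx.class_log2_induction("ethylene_late", "CA", t0, cfg) == 0.0
        assert hx.class_log2_induction("ethylene_late", "CA", t1, cfg) == 2.0
        assert hx.class_log2_induction("ethylene_late", "MCPCA", t1, cfg) == 0.0
        assert hx.class_log2_induction("maturation", "A10", 1, cfg) == 2.0
        assert hx.class_log2_induction("null", "CA", t1, cfg) == 0.0

    def test_planted_targets_track_parent_tf(self, small_sim):
        # planted-edge targets carry more mutual information with their
        # parent TF than with random other TFs
        from sklearn.feature_selection import mutual_info_regression

        _, counts, _, truth = small_sim
        logc = np.log1p(counts)
        rng = np.random.default_rng(0)
        wins = 0
        edges = sorted(truth.planted_edges)[:20]
        for tf, target in edges:
            y = logc.loc[target].to_numpy()
            mi_parent = mutual_info_regression(
                logc.loc[[tf]].T.to_numpy(), y, random_state=0
            )[0]
            others = [t for t in truth.tf_ids if t != tf]
            decoys = rng.choice(others, 3, replace=False)
            mi_decoy = np.mean(
                [
                    mutual_info_regression(
                        logc.loc[[d]].T.to_numpy(), y, random_state=0
                    )[0]
                    for d in decoys
                ]
            )
            wins += mi_parent > mi_decoy
        assert wins >= 18


@pytest.fixture(scope="module")
def seqs(small_sim):
    _, _, _, truth = small_sim
    return truth, hx.simulate_sequences(truth, seed=11)


class TestSequences:

    def test_motif_genes_have_hits_others_none(self, seqs):
        truth, sim = seqs
        for gene, seq in sim.upstream.items():
            hits = scan_motif(seq, HRPE, seq_id=gene)
            if gene in truth.motif_genes:
                assert hits, f"{gene} should carry an HRPE"
                assert sim.hrpe_offsets[gene] in {h.offset for h in hits}
            else:
                assert not hits, f"{gene} should be HRPE-free"

    def test_degron_tfs_translate_to_mcgga_iv(self, seqs):
        truth, sim = seqs
        for tf, cds in sim.cds.items():
            protein = translate_cds(cds)
            assert hx.has_n_degron(protein) == (tf in truth.degron_tfs)

    def test_upstream_length_and_alphabet(self, seqs):
        _, sim = seqs
        seq = next(iter(sim.upstream.values()))
        assert len(seq) == 1000
        assert set(seq) <= set("ACGT")

    def test_too_short_window_rejected(self, seqs):
        truth, _ = seqs
        with pytest.raises(ValueError):
            hx.simulate_sequences(truth, upstream_len=5)
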