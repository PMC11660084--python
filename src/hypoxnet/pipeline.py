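"""End-to-end orchestration: simulate/load -> normalize -> DE -> sets ->
network -> motifs -> enrichment, emitting a deterministic report bundle.

Every stage is also usable on its own through the library API; this
module just wires them together under one config and writes the standard
output files (set TSVs, set-size-vs-time JSON, edge lists, TF
classification table, motif presence tables, enrichment tables and a run
log with the thresholds and seed used).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as hio
from .de import (
    drop_all_zero_genes,
    estimate_size_factors,
    normalize,
    run_pooled_contrasts,
    run_timepoint_contrasts,
)
from .design import HYPOXIC, NORMOXIC
from .enrich import enrich
from .grn import (
    RegulatoryNetwork,
    classify_network_tfs,
    extract_hypoxia_subgraph,
    filter_expressed_tfs,
    filter_network_genes,
    infer_network,
    threshold_top_k,
)
from .motifs import HRPE, degron_census, presence_table
from .sets import build_hypoxia_sets, build_time_resolved_sets, set_to_frame
from .simulate import SimConfig, simulate_counts, simulate_sequences

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Inputs, thresholds, and seed for a full pipeline run.

    Either ``simulate`` is set (self-contained synthetic run) or the
    input paths must point at existing files.
    """

    simulate: SimConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    tf_list_path: str | None = None
    upstream_fasta: str | None = None
    cds_fasta: str | None = None
    term_map_path: str | None = None
    lfc_min: float = 1.0
    alpha: float = 0.05
    top_k: int = 5
    min_degree: int = 10
    net_min_samples: int = 10
    net_min_value: float = 3.0
    tf_min_samples: int = 3
    tf_min_count: float = 10.0
    n_trees: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lfc_min", "alpha", "top_k", "min_degree", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None:
            for name in ("counts_path", "metadata_path"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError("either simulate or counts/metadata paths required")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name}: no such file {path!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimConfig(**sim) if isinstance(sim, dict) else None, **raw)
        return cfg


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def _pooled_pairs() -> list[tuple[str, str]]:
    pairs = [(h, n) for h in HYPOXIC for n in NORMOXIC]
    pairs += [("CA", "MCPCA"), ("MCPCA", "CA")]
    return pairs


def run_all(config: RunConfig, outdir) -> dict[str, Any]:
    """Run every stage and write the report bundle under ``outdir``.

    Returns the in-memory results keyed by stage. Two runs with the same
    config produce byte-identical files.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}

    # -- inputs ------------------------------------------------------------
    @_stage("input")
    def _load():
        if config.simulate is not None:
            counts, metadata, truth = simulate_counts(config.simulate)
            seqs = simulate_sequences(truth, seed=config.simulate.seed)
            upstream, cds = seqs.upstream, seqs.cds
            tf_list = list(truth.tf_ids)
            months = list(config.simulate.longterm_months)
        else:
            counts = hio.read_counts_tsv(config.counts_path)
            metadata = hio.read_metadata_tsv(config.metadata_path)
            truth = None
            tf_list = (
                hio.read_tf_list(config.tf_list_path) if config.tf_list_path else []
            )
            upstream = (
                hio.read_fasta(config.upstream_fasta) if config.upstream_fasta else {}
            )
            cds = hio.read_fasta(config.cds_fasta) if config.cds_fasta else {}
            months = sorted(
                metadata.loc[metadata["treatment"] == "CA", "timepoint"].unique()
            )
        return counts, metadata, truth, tf_list, upstream, cds, months

    counts, metadata, truth, tf_list, upstream, cds, months = _load()
    bundle["counts"], bundle["metadata"], bundle["truth"] = counts, metadata, truth

    # -- normalization -----------------------------------------------------
    @_stage("normalize")
    def _norm():
        expressed = drop_all_zero_genes(counts)
        s = estimate_size_factors(expressed)
        return expressed, s, normalize(expressed, s)

    expressed, size_factors, norm = _norm()
    size_factors.to_csv(out / "size_factors.tsv", sep="\t", header=True)
    bundle["size_factors"], bundle["norm"] = size_factors, norm

    # -- differential expression and set logic -----------------------------
    @_stage("contrast_sets")
    def _sets():
        pooled = run_pooled_contrasts(norm, metadata, _pooled_pairs())
        hyp = build_hypoxia_sets(pooled, config.lfc_min, config.alpha)
        timed = run_timepoint_contrasts(
            norm, metadata, [("CA", "MCP"), ("MCPCA", "MCP"), ("CA", "MCPCA")], months
        )
        tsets = build_time_resolved_sets(timed, months, config.lfc_min, config.alpha)
        return pooled, hyp, timed, tsets

    pooled, hyp_sets, timed, time_sets = _sets()
    for (a, b), table in pooled.items():
        table.to_csv(out / f"contrast_{a}_vs_{b}.tsv", sep="\t")
    set_to_frame(hyp_sets.hypoxia_all, "hypoxia_all").to_csv(
        out / "set_hypoxia_all.tsv", sep="\t", index=False
    )
    set_to_frame(hyp_sets.ca_only, "ca_only").to_csv(
        out / "set_ca_only.tsv", sep="\t", index=False
    )
    set_to_frame(hyp_sets.mcpca_only, "mcpca_only").to_csv(
        out / "set_mcpca_only.tsv", sep="\t", index=False
    )
    sizes = time_sets.sizes()
    sizes.to_csv(out / "set_sizes_by_timepoint.tsv", sep="\t", index=False)
    (out / "set_sizes_by_timepoint.json").write_text(
        json.dumps(sizes.to_dict(orient="list"), indent=1) + "\n"
    )
    bundle["pooled"], bundle["hypoxia_sets"] = pooled, hyp_sets
    bundle["time_sets"] = time_sets

    # -- regulatory network -------------------------------------------------
    @_stage("network")
    def _network():
        filtered = filter_network_genes(
            norm, config.net_min_samples, config.net_min_value
        )
        tfs = filter_expressed_tfs(
            expressed, tf_list, config.tf_min_samples, config.tf_min_count
        )
        tfs = [t for t in tfs if t in filtered.index]
        targets = sorted(set(hyp_sets.hypoxia_all) & set(filtered.index))
        if truth is not None:
            targets = sorted(
                set(targets)
                | ({t for _, t in truth.planted_edges} & set(filtered.index))
            )
        if len(tfs) < 2 or not targets:
            empty = RegulatoryNetwork(
                pd.DataFrame(columns=["tf", "target", "importance"])
            )
            return tfs, empty, empty, pd.DataFrame(columns=["tf", "x", "y", "label"])
        net = infer_network(
            filtered,
            tfs,
            targets=targets,
            n_trees=config.n_trees,
            seed=config.seed,
        )
        top = threshold_top_k(net, config.top_k)
        sub = extract_hypoxia_subgraph(top, hyp_sets.hypoxia_all, config.min_degree)
        roles = classify_network_tfs(
            sub, hyp_sets.hypoxia_all, hyp_sets.ethylene_marked
        )
        return tfs, top, sub, roles

    tfs, top_net, hyp_net, tf_roles = _network()
    top_net.edges.to_csv(out / "network_top_edges.tsv", sep="\t", index=False)
    hyp_net.edges.to_csv(out / "network_hypoxia_subgraph.tsv", sep="\t", index=False)
    top_net.r2.rename("r2").to_csv(out / "network_r2.tsv", sep="\t", index_label="gene")
    tf_roles.to_csv(out / "tf_classification.tsv", sep="\t", index=False)
    bundle["tfs"], bundle["network"], bundle["hypoxia_network"] = tfs, top_net, hyp_net
    bundle["tf_roles"] = tf_roles

    # -- motif annotation ---------------------------------------------------
    @_stage("motifs")
    def _motifs():
        hrpe = presence_table(upstream, HRPE) if upstream else pd.DataFrame(
            columns=["seq_id", "n_hits", "present"]
        )
        degron = degron_census(cds) if cds else []
        return hrpe, degron

    hrpe_table, degron_ids = _motifs()
    hrpe_table.to_csv(out / "hrpe_presence.tsv", sep="\t", index=False)
    (out / "degron_census.txt").write_text("\n".join(degron_ids) + "\n")
    bundle["hrpe"], bundle["degron"] = hrpe_table, degron_ids

    # -- enrichment ---------------------------------------------------------
    @_stage("enrichment")
    def _enrich():
        universe = set(norm.index)
        if config.term_map_path:
            from .enrich import read_term_map

            term_map = read_term_map(config.term_map_path)
        elif truth is not None:
            term_map = {
                f"class:{c}": truth.genes_of_class(c) & universe
                for c in sorted(set(truth.gene_class.values()))
            }
        else:
            return pd.DataFrame()
        selected = hyp_sets.hypoxia_all & universe
        return enrich(selected, term_map, universe)

    enrichment = _enrich()
    enrichment.to_csv(out / "enrichment_hypoxia_all.tsv", sep="\t", index=False)
    bundle["enrichment"] = enrichment

    # -- ground-truth recovery (simulate mode only) -------------------------
    if truth is not None:
        recovery = _recovery_report(
            truth, hyp_sets, time_sets, top_net, months
        )
        (out / "recovery_report.json").write_text(
            json.dumps(recovery, indent=1, sort_keys=True) + "\n"
        )
        bundle["recovery"] = recovery

    log = {
        "package_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "lfc_min": config.lfc_min,
            "alpha": config.alpha,
            "top_k": config.top_k,
            "min_degree": config.min_degree,
            "net_min_samples": config.net_min_samples,
            "net_min_value": config.net_min_value,
            "tf_min_samples": config.tf_min_samples,
            "tf_min_count": config.tf_min_count,
            "n_trees": config.n_trees,
        },
        "simulate": dataclasses.asdict(config.simulate) if config.simulate else None,
        "n_genes_tested": int(len(norm)),
        "n_samples": int(len(metadata)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")
    bundle["log"] = log
    return bundle


def _recovery_report(truth, hyp_sets, time_sets, network, months) -> dict[str, Any]:
    """Sensitivity/precision of the planted structure."""

    def sens_prec(recovered: set[str], planted: set[str]) -> dict[str, float]:
        tp = len(recovered & planted)
        return {
            "sensitivity": tp / len(planted) if planted else float("nan"),
            "precision": tp / len(recovered) if recovered else float("nan"),
            "n_planted": len(planted),
            "n_recovered": len(recovered),
        }

    hypoxia_planted = truth.genes_of_class("ndegron_sustained") | truth.genes_of_class(
        "ndegron_transient"
    )
    report: dict[str, Any] = {
        "hypoxia_all": sens_prec(hyp_sets.hypoxia_all, hypoxia_planted),
        "n_degron_by_timepoint": {
            str(t): sens_prec(
                time_sets.n_degron.get(t, set()),
                truth.genes_of_class("ndegron_sustained"),
            )
            for t in months
        },
        "ethylene_sizes": {
            str(t): len(time_sets.ethylene.get(t, set())) for t in months
        },
    }
    if len(network.edges):
        edge_set = set(zip(network.edges["tf"], network.edges["target"]))
        planted = truth.planted_edges
        hit = sum(1 for e in planted if e in edge_set)
        report["edge_recovery"] = {
            "recovered": hit,
            "planted": len(planted),
            "rate": hit / len(planted) if planted else float("nan"),
        }
    return report
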