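"""Synthetic count-matrix, metadata, and sequence generator.

Emulates a bulk 3'-RNA-seq time course of fruit under seven postharvest
storage treatments so that every downstream stage (normalization,
NB contrasts, contrast-set logic, network inference, motif scanning) can
be exercised with known ground truth.

Genes belong to one of five response archetypes:

``null``
    No treatment effect; baseline negative-binomial noise.
``ndegron_transient``
    Induced in both hypoxic treatments (CA, MCPCA); the induction decays
    linearly in log-mean from full strength at the first long-term
    timepoint to none at the last. Mimics the rapidly-induced-then-fading
    early hypoxia response.
``ndegron_sustained``
    Induced at full strength in CA and MCPCA at every long-term
    timepoint (ethylene-independent hypoxia response).
``ethylene_late``
    Induced only in CA (hypoxia with intact ethylene perception), rising
    linearly in log-mean from none at the first long-term timepoint to
    full strength at the last. Absent from MCPCA because 1-MCP blocks
    ethylene perception.
``maturation``
    Induced in the air treatments (A1, A10, A20) only, providing true
    negatives for the hypoxia set logic.

Transcription-factor genes additionally carry a per-sample Gaussian
latent on their log-mean; planted targets receive ``edge_strength``
times the same standardized latent, giving a log-linear TF->target
coupling recoverable by tree-ensemble importances.

Counts are drawn gene-by-sample from NB(mu, alpha) with
``var = mu + alpha * mu**2``; ``alpha = 0`` degenerates to Poisson.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .design import HYPOXIC, LONG_TERM, SHORT_TERM
from .motifs import HRPE, IUPAC_CODES, scan_motif, translate_cds, has_n_degron

GENE_CLASSES: tuple[str, ...] = (
    "null",
    "ndegron_transient",
    "ndegron_sustained",
    "ethylene_late",
    "maturation",
)

_DEFAULT_FRACTIONS: dict[str, float] = {
    "null": 0.70,
    "ndegron_transient": 0.08,
    "ndegron_sustained": 0.08,
    "ethylene_late": 0.08,
    "maturation": 0.06,
}


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for the simulator.

    Defaults reflect the long-term storage design: 7 monthly sampling
    points for the long-term treatments, 3 biological replicates per
    treatment x timepoint cell, a 4-fold (2 log2 units) induction for
    affected genes, and mild NB overdispersion typical of bulk RNA-seq
    with biological replicates.
    """

    n_genes: int = 2000
    n_tfs: int = 60
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    base_mean_log_range: tuple[float, float] = (np.log(50.0), np.log(2000.0))
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    n_reps: int = 3
    longterm_months: tuple[float, ...] = (2, 4, 5, 6, 7, 8, 9)
    shortterm_months: tuple[float, ...] = (0.25, 1, 2, 3)
    edge_strength: float = 0.3
    targets_per_tf: int = 5
    n_degron_tfs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_tfs <= 0:
            raise ValueError("n_genes and n_tfs must be positive")
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")
        if set(self.class_fractions) != set(GENE_CLASSES):
            raise ValueError(f"class_fractions must have keys {GENE_CLASSES}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValueError("class_fractions must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for name in ("longterm_months", "shortterm_months"):
            months = tuple(getattr(self, name))
            if not months:
                raise ValueError(f"{name} must be non-empty")
            if any(b <= a for a, b in zip(months, months[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, months)
        if self.targets_per_tf < 0 or self.n_degron_tfs < 0:
            raise ValueError("targets_per_tf and n_degron_tfs must be >= 0")
        if self.n_tfs * self.targets_per_tf > self.n_genes - self.n_tfs:
            raise ValueError("not enough non-TF genes for the requested planted edges")


@dataclass
class GroundTruth:
    """Planted structure behind a simulated dataset."""

    gene_class: dict[str, str]
    planted_edges: set[tuple[str, str]]
    motif_genes: set[str]
    degron_tfs: set[str]
    tf_ids: list[str]

    def __post_init__(self) -> None:
        tfs = set(self.tf_ids)
        if any(tf not in tfs for tf, _ in self.planted_edges):
            raise ValueError("planted edge with non-TF source")
        if not {g for _, g in self.planted_edges} <= set(self.gene_class):
            raise ValueError("planted edge target outside gene universe")

    def genes_of_class(self, cls: str) -> set[str]:
        return {g for g, c in self.gene_class.items() if c == cls}


@dataclass
class SimSequences:
    """Upstream and coding sequences with the planted-motif bookkeeping."""

    upstream: dict[str, str]
    cds: dict[str, str]
    hrpe_offsets: dict[str, int]


def _rng(seed: int, label: str) -> np.random.Generator:
    # independent, order-insensitive stream per purpose
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def simulate_design(config: SimConfig) -> pd.DataFrame:
    """Sample metadata for the 7-treatment design.

    PreTreat appears at the single timepoint 0; A1/A10/A20 follow the
    short-term grid; MCP/CA/MCPCA follow the long-term monthly grid.
    """
    rows = []
    cells = [("PreTreat", 0.0)]
    cells += [(t, m) for t in SHORT_TERM for m in config.shortterm_months]
    cells += [(t, m) for t in LONG_TERM for m in config.longterm_months]
    for treatment, month in cells:
        for rep in range(1, config.n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{treatment}_t{month:g}_r{rep}",
                    "treatment": treatment,
                    "timepoint": float(month),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def class_log2_induction(
    cls: str, treatment: str, timepoint: float, config: SimConfig
) -> float:
    """Planted log2 induction for one gene class in one design cell."""
    eff = config.effect_log2fc
    t0, t1 = config.longterm_months[0], config.longterm_months[-1]
    span = t1 - t0 if t1 > t0 else 1.0
    if cls == "ndegron_sustained" and treatment in HYPOXIC:
        return eff
    if cls == "ndegron_transient" and treatment in HYPOXIC:
        return eff * (t1 - timepoint) / span
    if cls == "ethylene_late" and treatment == "CA":
        return eff * (timepoint - t0) / span
    if cls == "maturation" and treatment in SHORT_TERM:
        return eff
    return 0.0


def _assign_classes(config: SimConfig, non_tf_genes: list[str]) -> dict[str, str]:
    n = len(non_tf_genes)
    counts = {c: int(np.floor(config.class_fractions[c] * n)) for c in GENE_CLASSES}
    # distribute rounding remainder by descending fractional part
    rem = n - sum(counts.values())
    frac = sorted(
        GENE_CLASSES,
        key=lambda c: (config.class_fractions[c] * n) % 1.0,
        reverse=True,
    )
    for c in frac[:rem]:
        counts[c] += 1
    labels = [c for c in GENE_CLASSES for _ in range(counts[c])]
    perm = _rng(config.seed, "classes").permutation(n)
    return {non_tf_genes[i]: labels[k] for k, i in enumerate(perm)}


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the count matrix.

    Returns ``(counts, metadata, truth)`` where ``counts`` is a
    genes x samples integer DataFrame and ``metadata`` the table from
    :func:`simulate_design`. The same config (including seed) always
    produces identical output.
    """
    meta = simulate_design(config)
    width = len(str(config.n_genes))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(config.n_genes)]

    pick = _rng(config.seed, "roles")
    tf_idx = np.sort(pick.choice(config.n_genes, size=config.n_tfs, replace=False))
    tf_ids = [gene_ids[i] for i in tf_idx]
    non_tf = [g for g in gene_ids if g not in set(tf_ids)]

    gene_class = _assign_classes(config, non_tf)
    for tf in tf_ids:  # TFs act through their latent, not a planted class
        gene_class[tf] = "null"

    # targets come from null-class genes so the regulatory coupling and the
    # planted treatment effects stay orthogonal ground truths
    null_pool = [g for g in non_tf if gene_class[g] == "null"]
    n_targets = config.n_tfs * config.targets_per_tf
    if n_targets > len(null_pool):
        raise ValueError("not enough null-class genes for the requested planted edges")
    target_pool = pick.choice(len(null_pool), size=n_targets, replace=False)
    planted_edges = {
        (tf_ids[j // config.targets_per_tf], null_pool[target_pool[j]])
        for j in range(n_targets)
    }
    parent_of = {t: tf for tf, t in planted_edges}
    degron_tfs = set(
        pick.choice(tf_ids, size=min(config.n_degron_tfs, config.n_tfs), replace=False)
    )
    motif_genes = {
        g
        for g, c in gene_class.items()
        if c in ("ndegron_transient", "ndegron_sustained")
    }
    truth = GroundTruth(gene_class, planted_edges, motif_genes, degron_tfs, tf_ids)

    base = np.exp(
        _rng(config.seed, "base").uniform(*config.base_mean_log_range, config.n_genes)
    )
    n_samples = len(meta)
    z = _rng(config.seed, "latent").standard_normal((config.n_tfs, n_samples))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
    z_by_tf = {tf: z[k] for k, tf in enumerate(tf_ids)}

    log2_ind = np.zeros((config.n_genes, n_samples))
    cell_cache: dict[tuple[str, str, float], float] = {}
    treatments = meta["treatment"].to_numpy()
    months = meta["timepoint"].to_numpy()
    for gi, g in enumerate(gene_ids):
        cls = gene_class[g]
        if cls == "null":
            continue
        for si in range(n_samples):
            key = (cls, treatments[si], months[si])
            if key not in cell_cache:
                cell_cache[key] = class_log2_induction(*key, config)
            log2_ind[gi, si] = cell_cache[key]

    log_mu = np.log(base)[:, None] + np.log(2.0) * log2_ind
    for gi, g in enumerate(gene_ids):
        if g in z_by_tf:
            log_mu[gi] += config.edge_strength * z_by_tf[g]
        elif g in parent_of:
            log_mu[gi] += config.edge_strength * z_by_tf[parent_of[g]]
    mu = np.exp(log_mu)

    draw = _rng(config.seed, "counts")
    if config.dispersion == 0:
        values = draw.poisson(mu)
    else:
        size = 1.0 / config.dispersion
        p = size / (size + mu)
        values = draw.negative_binomial(size, p)
    counts = pd.DataFrame(values, index=gene_ids, columns=meta["sample_id"].tolist())
    counts.index.name = "gene_id"
    return counts, meta, truth


# --- sequence simulation ---------------------------------------------------

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _realize_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(sorted(IUPAC_CODES[c])) for c in pattern)


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = _random_seq(rng, 3)
        if codon not in _STOPS:
            return codon


def _degron_start(rng: np.random.Generator) -> str:
    # ATG TGY GGN GGN GCN then ATH (Ile) or GTN (Val)
    tail = _realize_iupac(rng, "ATH") if rng.random() < 0.5 else _realize_iupac(rng, "GTN")
    return "ATG" + _realize_iupac(rng, "TGYGGNGGNGCN") + tail


def simulate_sequences(
    truth: GroundTruth,
    upstream_len: int = 1000,
    *,
    cds_codons: int = 60,
    seed: int = 0,
) -> SimSequences:
    """Upstream windows for every gene and CDS for every TF.

    Genes in ``truth.motif_genes`` carry at least one exact HRPE instance
    (random realization of the ambiguity codes) at a recorded offset; all
    other upstream windows are HRPE-free by rejection sampling on both
    strands. TFs in ``truth.degron_tfs`` get a CDS whose translation
    starts MCGGAI or MCGGAV; other TF CDS are degron-free.
    """
    if upstream_len < len(HRPE):
        raise ValueError("upstream_len shorter than the HRPE motif")
    rng = _rng(seed, "sequences")
    upstream: dict[str, str] = {}
    offsets: dict[str, int] = {}
    for gene in sorted(truth.gene_class):
        if gene in truth.motif_genes:
            seq = _random_seq(rng, upstream_len)
            off = int(rng.integers(0, upstream_len - len(HRPE) + 1))
            seq = seq[:off] + _realize_iupac(rng, HRPE) + seq[off + len(HRPE):]
            upstream[gene] = seq
            offsets[gene] = off
        else:
            while True:
                seq = _random_seq(rng, upstream_len)
                if not scan_motif(seq, HRPE):
                    break
            upstream[gene] = seq

    cds: dict[str, str] = {}
    for tf in sorted(truth.tf_ids):
        if tf in truth.degron_tfs:
            body = _degron_start(rng)
            body += "".join(_random_codon(rng) for _ in range(cds_codons - 7))
        else:
            while True:
                body = "ATG" + "".join(_random_codon(rng) for _ in range(cds_codons - 2))
                if not has_n_degron(translate_cds(body)):
                    break
        cds[tf] = body + "TAA"
    return SimSequences(upstream, cds, offsets)
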