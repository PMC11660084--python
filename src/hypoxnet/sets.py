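"""Contrast-set logic classifying the hypoxia response.

Three constructions over up-regulation calls from pairwise contrasts:

* the hypoxia-upregulated set: genes up in a hypoxic treatment (CA or
  MCPCA) versus *every* normoxic treatment (PreTreat, A1, A10, A20, MCP);
* the CA-only / MCPCA-only exclusive subsets: genes up in the focal
  hypoxic treatment versus all six other treatments, isolating the
  ethylene-dependent (CA-only) and ethylene-blocked (MCPCA-only) parts
  of the response;
* per-timepoint "n-degron" (up in CA and MCPCA vs MCP: hypoxia response
  independent of ethylene perception) and "ethylene" (up in CA vs both
  MCP and MCPCA: hypoxia response requiring ethylene perception) sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .de import call_upregulated
from .design import HYPOXIC, NORMOXIC, TREATMENTS

PooledTables = Mapping[tuple[str, str], pd.DataFrame]
TimeTables = Mapping[tuple[str, str, float], pd.DataFrame]


@dataclass
class HypoxiaSets:
    """The hypoxia-upregulated set and its treatment-exclusive subsets."""

    hypoxia_all: set[str]
    ca_only: set[str]
    mcpca_only: set[str]

    def __post_init__(self) -> None:
        if not self.ca_only <= self.hypoxia_all:
            raise ValueError("ca_only must be a subset of hypoxia_all")
        if not self.mcpca_only <= self.hypoxia_all:
            raise ValueError("mcpca_only must be a subset of hypoxia_all")
        if self.ca_only & self.mcpca_only:
            raise ValueError("ca_only and mcpca_only must be disjoint")

    @property
    def ethylene_marked(self) -> set[str]:
        """Union of the two exclusive subsets (the ethylene-marked genes
        counted on the TF-role classifier's y-axis)."""
        return self.ca_only | self.mcpca_only


@dataclass
class TimeResolvedSets:
    """Per-timepoint n-degron and ethylene gene sets."""

    n_degron: dict[float, set[str]] = field(default_factory=dict)
    ethylene: dict[float, set[str]] = field(default_factory=dict)

    def sizes(self) -> pd.DataFrame:
        months = sorted(set(self.n_degron) | set(self.ethylene))
        return pd.DataFrame(
            {
                "timepoint": months,
                "n_degron": [len(self.n_degron.get(t, set())) for t in months],
                "ethylene": [len(self.ethylene.get(t, set())) for t in months],
            }
        )


def _calls(
    tables: PooledTables,
    pairs: Iterable[tuple[str, str]],
    lfc_min: float,
    alpha: float,
) -> dict[tuple[str, str], set[str]]:
    calls = {}
    for pair in pairs:
        if pair not in tables:
            raise KeyError(f"missing contrast {pair[0]} vs {pair[1]}")
        calls[pair] = call_upregulated(tables[pair], lfc_min, alpha)
    return calls


def hypoxia_upregulated_set(
    tables: PooledTables,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    *,
    mode: str = "exists_all",
) -> set[str]:
    """Genes up-regulated under hypoxia versus every normoxic treatment.

    ``mode='exists_all'`` (default): a gene is included iff there is a
    hypoxic treatment H with the gene called up in H vs N for *all* five
    normoxic N. ``mode='any_pair'`` relaxes this to being called up in
    any single hypoxic-vs-normoxic pair.
    """
    pairs = [(h, n) for h in HYPOXIC for n in NORMOXIC]
    calls = _calls(tables, pairs, lfc_min, alpha)
    if mode == "exists_all":
        out: set[str] = set()
        for h in HYPOXIC:
            per_h = [calls[(h, n)] for n in NORMOXIC]
            out |= set.intersection(*per_h)
        return out
    if mode == "any_pair":
        return set.union(*calls.values())
    raise ValueError(f"unknown mode {mode!r}")


def exclusive_subset(
    tables: PooledTables,
    focal: str,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> set[str]:
    """Genes up in the focal hypoxic treatment versus all six others."""
    if focal not in HYPOXIC:
        raise ValueError(f"focal treatment must be hypoxic, got {focal!r}")
    others = [t for t in TREATMENTS if t != focal]
    calls = _calls(tables, [(focal, o) for o in others], lfc_min, alpha)
    return set.intersection(*calls.values())


def build_hypoxia_sets(
    tables: PooledTables,
    lfc_min: float = 1.0,
    alpha: float = 0.05,
    *,
    mode: str = "exists_all",
) -> HypoxiaSets:
    """Assemble the hypoxia set and its exclusive subsets in one pass.

    The exclusive subsets are intersected with the hypoxia set so the
    declared subset invariants hold on any input.
    """
    hypoxia_all = hypoxia_upregulated_set(tables, lfc_min, alpha, mode=mode)
    ca = exclusive_subset(tables, "CA", lfc_min, alpha) & hypoxia_all
    mcpca = exclusive_subset(tables, "MCPCA", lfc_min, alpha) & hypoxia_all
    return HypoxiaSets(hypoxia_all, ca, mcpca)


def _check_timepoint(tables: TimeTables, t: float) -> None:
    known = {key[2] for key in tables}
    if t not in known:
        raise KeyError(f"timepoint {t} not among long-term timepoints {sorted(known)}")


def n_degron_set(
    tables: TimeTables, t: float, lfc_min: float = 1.0, alpha: float = 0.05
) -> set[str]:
    """Genes up in both CA vs MCP and MCPCA vs MCP at timepoint ``t``."""
    _check_timepoint(tables, t)
    for key in (("CA", "MCP", t), ("MCPCA", "MCP", t)):
        if key not in tables:
            raise KeyError(f"missing contrast {key[0]} vs {key[1]} at t={t}")
    up_ca = call_upregulated(tables[("CA", "MCP", t)], lfc_min, alpha)
    up_mcpca = call_upregulated(tables[("MCPCA", "MCP", t)], lfc_min, alpha)
    return up_ca & up_mcpca


def ethylene_set(
    tables: TimeTables, t: float, lfc_min: float = 1.0, alpha: float = 0.05
) -> set[str]:
    """Genes up in CA vs MCP and in CA vs MCPCA at timepoint ``t``."""
    _check_timepoint(tables, t)
    for key in (("CA", "MCP", t), ("CA", "MCPCA", t)):
        if key not in tables:
            raise KeyError(f"missing contrast {key[0]} vs {key[1]} at t={t}")
    up_vs_mcp = call_upregulated(tables[("CA", "MCP", t)], lfc_min, alpha)
    up_vs_mcpca = call_upregulated(tables[("CA", "MCPCA", t)], lfc_min, alpha)
    return up_vs_mcp & up_vs_mcpca


def build_time_resolved_sets(
    tables: TimeTables,
    timepoints: Iterable[float],
    lfc_min: float = 1.0,
    alpha: float = 0.05,
) -> TimeResolvedSets:
    out = TimeResolvedSets()
    for t in timepoints:
        out.n_degron[t] = n_degron_set(tables, t, lfc_min, alpha)
        out.ethylene[t] = ethylene_set(tables, t, lfc_min, alpha)
    return out


def set_to_frame(genes: set[str], label: str) -> pd.DataFrame:
    """Sorted two-column table for deterministic set output files."""
    return pd.DataFrame({"gene_id": sorted(genes), "set": label})
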