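"""Hypergeometric over-representation test for gene sets.

A generic term -> genes map (GO slims, pathway sets, custom panels) is
tested against a selected gene set drawn from a declared universe. The
per-term p-value is the upper tail P(X >= overlap) of
Hypergeometric(|universe|, |term|, |selected|); adjustment is
Benjamini-Hochberg across the tested terms.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def enrich(
    selected: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-term overlap, hypergeometric p and BH-adjusted p, sorted by p.

    ``selected`` must be a subset of ``universe``; term genes outside the
    universe are ignored for the margins. Raises with the offending IDs
    when the subset precondition fails.
    """
    uni = set(universe)
    sel = set(selected)
    stray = sorted(sel - uni)
    if stray:
        raise ValueError(f"selected genes outside the universe: {stray}")
    M, n_sel = len(uni), len(sel)
    rows = []
    for term in sorted(term_map):
        genes = set(term_map[term]) & uni
        overlap = len(genes & sel)
        p = float(hypergeom.sf(overlap - 1, M, len(genes), n_sel))
        rows.append(
            {
                "term": term,
                "label": (labels or {}).get(term, ""),
                "term_size": len(genes),
                "overlap": overlap,
                "p": min(1.0, p),
            }
        )
    table = pd.DataFrame(rows, columns=["term", "label", "term_size", "overlap", "p"])
    if len(table):
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = pd.Series(dtype=float)
    return table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    out: dict[str, set[str]] = {}
    for term, gene in df.itertuples(index=False):
        out.setdefault(term, set()).add(gene)
    return out
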