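"""Tree-ensemble regulatory-network inference (GENIE3-style).

Each target gene's expression profile is regressed on the expression of
all candidate transcription factors (excluding the target itself when it
is a TF) with a random forest; the mean impurity-reduction importance of
each TF is the weight of the TF -> target edge, and the out-of-bag R^2
records how predictable the target is from TFs at all. The network is
then thresholded to the top-k TFs per target, restricted to the hypoxia
gene set, pruned of low-degree TFs, and each retained TF is classified
as a "standard" or "ethylene-mediated" hypoxia regulator by where its
per-category target counts fall relative to the scaled diagonal
``y = (y_max / x_max) * x``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance


@dataclass
class RegulatoryNetwork:
    """Weighted TF -> target edges plus per-target predictability."""

    edges: pd.DataFrame  # columns: tf, target, importance
    r2: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        cols = {"tf", "target", "importance"}
        if not cols <= set(self.edges.columns):
            raise ValueError(f"edges must have columns {sorted(cols)}")
        if (self.edges["tf"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        imp = self.edges["importance"].to_numpy(dtype=float)
        if not np.all(np.isfinite(imp)) or (imp < 0).any():
            raise ValueError("importances must be finite and >= 0")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.edges["tf"].unique())

    @property
    def targets(self) -> list[str]:
        return sorted(self.edges["target"].unique())

    def targets_of(self, tf: str) -> set[str]:
        return set(self.edges.loc[self.edges["tf"] == tf, "target"])

    def regulators_of(self, target: str) -> pd.DataFrame:
        sub = self.edges[self.edges["target"] == target]
        return sub.sort_values(["importance", "tf"], ascending=[False, True])

    def degree_table(self) -> pd.Series:
        return self.edges.groupby("tf")["target"].nunique().sort_values(ascending=False)


def filter_network_genes(
    norm: pd.DataFrame, min_samples: int = 10, min_value: float = 3.0
) -> pd.DataFrame:
    """Keep genes with >= min_value normalized expression in >= min_samples samples."""
    keep = (norm >= min_value).sum(axis=1) >= min_samples
    return norm.loc[keep]


def filter_expressed_tfs(
    raw_counts: pd.DataFrame,
    tf_list: Sequence[str],
    min_samples: int = 3,
    min_count: float = 10.0,
) -> list[str]:
    """TFs with a raw count strictly above min_count in >= min_samples samples."""
    kept = []
    for tf in tf_list:
        if tf not in raw_counts.index:
            warnings.warn(f"TF {tf!r} not in count matrix; skipped", stacklevel=2)
            continue
        if int((raw_counts.loc[tf] > min_count).sum()) >= min_samples:
            kept.append(tf)
    return kept


def _target_seed(seed: int, target: str) -> int:
    # order-independent per-target stream
    return (int(seed) * 2654435761 + zlib.crc32(target.encode())) % (2**31)


def infer_network(
    expr: pd.DataFrame,
    tfs: Sequence[str],
    *,
    targets: Sequence[str] | None = None,
    n_trees: int = 1000,
    max_features: str | int | float = "sqrt",
    importance: str = "impurity",
    seed: int = 0,
) -> RegulatoryNetwork:
    """Random-forest network over a genes x samples expression matrix.

    ``targets`` defaults to every gene in ``expr``; because each target is
    fit independently, restricting it is an exact shortcut when only a
    subgraph is needed. A constant target yields all-zero importances and
    an R^2 of 0. Per-target seeds derive from ``(seed, target)`` so
    results do not depend on row or column order.
    """
    tfs = sorted(set(tfs))
    if len(tfs) < 2:
        raise ValueError("need at least 2 candidate TFs")
    missing = [t for t in tfs if t not in expr.index]
    if missing:
        raise KeyError(f"TFs absent from expression matrix: {missing}")
    if targets is None:
        targets = list(expr.index)
    if importance not in ("impurity", "permutation"):
        raise ValueError("importance must be 'impurity' or 'permutation'")

    tf_expr = expr.loc[tfs].to_numpy(dtype=float).T  # samples x TFs
    rows = []
    r2: dict[str, float] = {}
    for target in targets:
        predictors = [t for t in tfs if t != target]
        if len(predictors) < 1:
            continue
        if target in expr.index:
            y = expr.loc[target].to_numpy(dtype=float)
        else:
            raise KeyError(f"target {target!r} absent from expression matrix")
        if target in tfs:
            cols = [i for i, t in enumerate(tfs) if t != target]
            X = tf_expr[:, cols]
        else:
            X = tf_expr
        if np.allclose(y, y[0]):
            r2[target] = 0.0
            for tf in predictors:
                rows.append((tf, target, 0.0))
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            oob_score=True,
            random_state=_target_seed(seed, target),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-sample OOB warnings
            rf.fit(X, y)
        r2[target] = float(rf.oob_score_) if np.isfinite(rf.oob_score_) else 0.0
        if importance == "impurity":
            imps = rf.feature_importances_
        else:
            perm = permutation_importance(
                rf, X, y, n_repeats=5, random_state=_target_seed(seed, target)
            )
            imps = np.maximum(perm.importances_mean, 0.0)
        for tf, w in zip(predictors, imps):
            rows.append((tf, target, float(w)))
    edges = pd.DataFrame(rows, columns=["tf", "target", "importance"])
    return RegulatoryNetwork(edges, pd.Series(r2, name="r2"))


def threshold_top_k(network: RegulatoryNetwork, k: int = 5) -> RegulatoryNetwork:
    """Keep the k highest-importance incoming edges per target.

    Ties at rank k break deterministically by (importance desc, tf asc).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = network.edges.sort_values(
        ["target", "importance", "tf"], ascending=[True, False, True]
    )
    kept = edges.groupby("target", sort=True).head(k).reset_index(drop=True)
    return RegulatoryNetwork(kept, network.r2.copy())


def extract_hypoxia_subgraph(
    network: RegulatoryNetwork,
    hypoxia_genes: Iterable[str],
    min_degree: int = 10,
) -> RegulatoryNetwork:
    """Restrict targets to the hypoxia set, then drop TFs regulating fewer
    than ``min_degree`` of the remaining targets."""
    hyp = set(hypoxia_genes)
    sub = network.edges[network.edges["target"].isin(hyp)]
    degree = sub.groupby("tf")["target"].nunique()
    keep_tfs = set(degree.index[degree >= min_degree])
    sub = sub[sub["tf"].isin(keep_tfs)].reset_index(drop=True)
    r2 = network.r2[network.r2.index.isin(hyp)] if len(network.r2) else network.r2
    return RegulatoryNetwork(sub, r2.copy())


def classify_tf(x: int, y: int, slope: float) -> str:
    """'ethylene_mediated' iff strictly above the line y = slope * x."""
    if x < 0 or y < 0:
        raise ValueError("target counts must be non-negative")
    if slope <= 0:
        raise ValueError("slope must be positive")
    return "ethylene_mediated" if y > slope * x else "standard"


def classify_network_tfs(
    network: RegulatoryNetwork,
    hypoxia_all: set[str],
    ethylene_marked: set[str],
    slope: float | None = None,
) -> pd.DataFrame:
    """Per-TF target counts and role labels.

    ``x`` counts "standard hypoxia" targets (hypoxia set minus the
    CA-only/MCPCA-only union); ``y`` counts targets in that union. The
    default slope is ``max(y) / max(x)`` over the network's TFs —
    the scaled diagonal of the target-count scatter. If no TF has a
    standard target, any TF with an ethylene-marked target is labelled
    ethylene_mediated (degenerate slope).
    """
    standard_pool = hypoxia_all - ethylene_marked
    rows = []
    for tf in network.tfs:
        targets = network.targets_of(tf)
        rows.append(
            {
                "tf": tf,
                "x": len(targets & standard_pool),
                "y": len(targets & ethylene_marked),
            }
        )
    table = pd.DataFrame(rows, columns=["tf", "x", "y"])
    if table.empty:
        table["label"] = pd.Series(dtype=str)
        return table
    x_max = int(table["x"].max())
    y_max = int(table["y"].max())
    if slope is None:
        if x_max == 0:
            table["label"] = np.where(table["y"] > 0, "ethylene_mediated", "standard")
            return table
        slope = y_max / x_max if y_max > 0 else None
        if slope is None or slope <= 0:
            table["label"] = "standard"
            return table
    table["label"] = [
        classify_tf(int(r.x), int(r.y), slope) for r in table.itertuples(index=False)
    ]
    return table


def focal_tf_subnetwork(
    network: RegulatoryNetwork,
    focal_tf_ids: Sequence[str],
    annotate_set: Iterable[str] = (),
) -> tuple[RegulatoryNetwork, pd.DataFrame, set[str]]:
    """Subgraph of the focal TFs plus their pairwise/all-way target overlaps.

    Returns ``(subgraph, overlap_table, all_focal_intersection)``; the
    subgraph's edge table gains an ``in_set`` flag for targets in
    ``annotate_set``.
    """
    focal = list(dict.fromkeys(focal_tf_ids))
    known = set(network.edges["tf"])
    unknown = [t for t in focal if t not in known]
    if unknown:
        raise KeyError(f"focal TFs not present in network: {unknown}")
    ann = set(annotate_set)
    sub = network.edges[network.edges["tf"].isin(focal)].reset_index(drop=True).copy()
    sub["in_set"] = sub["target"].isin(ann)
    pools = {tf: set(sub.loc[sub["tf"] == tf, "target"]) for tf in focal}
    rows = []
    for i, a in enumerate(focal):
        for b in focal[i + 1 :]:
            shared = pools[a] & pools[b]
            rows.append(
                {
                    "tf_a": a,
                    "tf_b": b,
                    "overlap": len(shared),
                    "overlap_in_set": len(shared & ann),
                }
            )
    overlap = pd.DataFrame(rows, columns=["tf_a", "tf_b", "overlap", "overlap_in_set"])
    all_shared = set.intersection(*pools.values()) if pools else set()
    subgraph = RegulatoryNetwork(sub[["tf", "target", "importance"]].copy(), network.r2.copy())
    subgraph.edges["in_set"] = sub["in_set"].to_numpy()
    return subgraph, overlap, all_shared


def to_networkx(network: RegulatoryNetwork):
    """Directed weighted graph for GraphML export or layout tools."""
    import networkx as nx

    g = nx.DiGraph()
    for row in network.edges.itertuples(index=False):
        g.add_edge(row.tf, row.target, importance=float(row.importance))
    return g


def write_graphml(network: RegulatoryNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(network), path)
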