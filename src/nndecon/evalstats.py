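"""Representation-quality statistics.

Two independent checks of how well a feature representation separates
primary from metastatic samples:

* Ward hierarchical clustering of the samples, viewed as a unit-edge graph
  (every dendrogram edge counts 1.0 regardless of merge height, so different
  feature scales are comparable).  MSD is the mean squared shortest-path
  distance between same-label leaf pairs; rMSD divides by the different-label
  counterpart; z-scores come from shuffling leaf labels.
* Per-pathway two-sample t-tests between primary and metastatic samples with
  Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import floyd_warshall
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DendrogramGraph",
    "GroupingMetrics",
    "ward_dendrogram",
    "all_pairs_unit_distances",
    "grouping_metrics",
    "differential_pathways",
]


@dataclass
class DendrogramGraph:
    """Dendrogram as an undirected tree with unit-length edges.

    Leaves are 0..n−1 (samples, each carrying a label); merge nodes are
    n..2n−2.
    """

    graph: nx.Graph
    leaves: list
    labels: dict  # leaf → label

    def __post_init__(self):
        if not nx.is_tree(self.graph):
            raise ValueError("dendrogram graph must be a tree")
        missing = [l for l in self.leaves if l not in self.labels]
        if missing:
            raise ValueError(f"leaves without labels: {missing}")


@dataclass
class GroupingMetrics:
    msd: float
    rmsd: float
    z_msd: float
    z_rmsd: float
    n_shuffles: int
    seed: int


def ward_dendrogram(X: np.ndarray, labels) -> DendrogramGraph:
    """Ward's minimum-variance clustering of the rows of X as a unit-edge tree."""
    X = np.asarray(X, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("one label per sample required")
    Z = linkage(X, method="ward")
    G = nx.Graph()
    for i in range(n):
        G.add_node(i)
    for step, (a, b, _, _) in enumerate(Z):
        merge = n + step
        G.add_edge(int(a), merge)
        G.add_edge(int(b), merge)
    return DendrogramGraph(
        graph=G, leaves=list(range(n)), labels=dict(enumerate(labels))
    )


def all_pairs_unit_distances(G: DendrogramGraph | nx.Graph) -> np.ndarray:
    """All-pairs shortest-path matrix with every edge counted as 1.0."""
    graph = G.graph if isinstance(G, DendrogramGraph) else G
    nodes = sorted(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    D = floyd_warshall(A, directed=False, unweighted=True)
    if np.isinf(D).any():
        raise ValueError("graph is disconnected")
    return D


def _msd_pair_stats(D, leaves, labels):
    """(MSD_same, MSD_different) over unordered leaf pairs."""
    same, diff = [], []
    for a in range(len(leaves)):
        for b in range(a + 1, len(leaves)):
            d2 = D[leaves[a], leaves[b]] ** 2
            (same if labels[a] == labels[b] else diff).append(d2)
    if not same or not diff:
        raise ValueError("both same- and different-label leaf pairs are required")
    return float(np.mean(same)), float(np.mean(diff))


def grouping_metrics(
    G: DendrogramGraph, n_shuffles: int = 1000, seed: int = 0
) -> GroupingMetrics:
    """MSD, rMSD and their shuffle z-scores for a labeled dendrogram.

    Smaller values mean same-label samples sit closer in the tree.  The null
    distribution permutes leaf labels ``n_shuffles`` times (seeded);
    z = (observed − shuffle mean) / shuffle std.
    """
    labels = [G.labels[l] for l in G.leaves]
    if len(set(labels)) < 2:
        raise ValueError("need at least two distinct labels")
    D = all_pairs_unit_distances(G)
    msd_same, msd_diff = _msd_pair_stats(D, G.leaves, labels)
    rmsd = msd_same / msd_diff
    rng = np.random.default_rng(seed)
    null_msd = np.empty(n_shuffles)
    null_rmsd = np.empty(n_shuffles)
    lab = np.array(labels, dtype=object)
    for i in range(n_shuffles):
        shuffled = lab[rng.permutation(len(lab))]
        s, d = _msd_pair_stats(D, G.leaves, list(shuffled))
        null_msd[i] = s
        null_rmsd[i] = s / d
    return GroupingMetrics(
        msd=msd_same,
        rmsd=rmsd,
        z_msd=(msd_same - null_msd.mean()) / null_msd.std(),
        z_rmsd=(rmsd - null_rmsd.mean()) / null_rmsd.std(),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def differential_pathways(
    B_P: np.ndarray,
    stages,
    alpha: float = 0.05,
    names=None,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-pathway t-test (primary vs metastatic) with BH FDR control.

    Unpaired equal-variance Student's t by default; ``paired=True`` runs a
    paired t-test on columns ordered so that sample j of one group matches
    sample j of the other.  Zero-variance rows yield p = 1.  Direction is
    "gain" when the metastatic mean exceeds the primary mean.
    """
    B_P = np.asarray(B_P, float)
    stages = np.asarray(list(stages))
    pri = B_P[:, stages == "primary"]
    met = B_P[:, stages == "metastatic"]
    if pri.shape[1] < 2 or met.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if paired:
        if pri.shape[1] != met.shape[1]:
            raise ValueError("paired test needs equal group sizes")
        t, p = stats.ttest_rel(met, pri, axis=1)
    else:
        t, p = stats.ttest_ind(met, pri, axis=1, equal_var=True)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    if names is None:
        names = [f"pathway{i + 1}" for i in range(B_P.shape[0])]
    return pd.DataFrame(
        {
            "pathway": list(names),
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": np.where(met.mean(axis=1) > pri.mean(axis=1), "gain", "loss"),
            "significant": fdr < alpha,
        }
    )
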