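"""Sibship networks per genetic cluster and their transitivity.

Each cluster becomes a simple undirected graph: nodes are individuals,
edges are dyads classified full- or half-sib (the distinction is kept as
an edge attribute but ignored by the topology).  Interconnectedness is
summarized by the mean local transitivity (clustering coefficient): per
node, the fraction of its neighbor pairs that are themselves connected,
with nodes of degree < 2 contributing 0 -- so a cluster of disjoint sib
pairs scores exactly 0, and a few large sib groups score near 1.
Significance is assessed against Erdos-Renyi G(n, m) graphs of identical
order and size.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .genotype import GenotypeTableError
from .results import TestResult
from .sibship import DyadClassification

__all__ = ["build_sib_graph", "mean_local_transitivity", "er_transitivity_test",
           "sample_gnm_adjacency"]


def build_sib_graph(cluster_members: list[str], dyads: DyadClassification) -> nx.Graph:
    """Graph on the cluster's individuals with an edge per FS/HS dyad.

    Requires a classification row for every within-cluster pair.
    """
    g = nx.Graph()
    g.add_nodes_from(cluster_members)
    members = set(cluster_members)
    df = dyads.table
    inside = df[df["id1"].isin(members) & df["id2"].isin(members)]
    n = len(cluster_members)
    if len(inside) < n * (n - 1) // 2:
        raise GenotypeTableError("dyad classification missing within-cluster pairs")
    for _, row in inside.iterrows():
        if row["label"] in ("FS", "HS"):
            g.add_edge(row["id1"], row["id2"], kind=row["label"])
    return g


def mean_local_transitivity(graph: nx.Graph) -> tuple[float, float]:
    """Mean and SD (across nodes) of the local clustering coefficient.

    Degree-0 and degree-1 nodes contribute 0.  Raises on an empty graph.
    """
    if graph.number_of_nodes() == 0:
        raise GenotypeTableError("empty graph")
    local = np.asarray(list(nx.clustering(graph).values()), float)
    return float(local.mean()), float(local.std(ddof=0))


def sample_gnm_adjacency(n: int, m: int, n_sim: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Boolean adjacency stack (n_sim, n, n) of uniform G(n, m) graphs.

    Each replicate picks m distinct node pairs uniformly without
    replacement, so simulated graphs are simple with exactly m edges.
    """
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    adj = np.zeros((n_sim, n, n), dtype=bool)
    for s in range(n_sim):
        pick = rng.choice(n_pairs, size=m, replace=False)
        adj[s, iu[pick], ju[pick]] = True
    adj |= adj.transpose(0, 2, 1)
    return adj


def _batch_mean_transitivity(adj: np.ndarray) -> np.ndarray:
    """Mean local clustering coefficient per adjacency matrix in the stack."""
    a = adj.astype(np.float64)
    deg = a.sum(axis=2)
    triangles = np.einsum("sij,sjk,ski->si", a, a, a) / 2.0
    pairs = deg * (deg - 1) / 2.0
    local = np.where(pairs > 0, triangles / np.maximum(pairs, 1.0), 0.0)
    return local.mean(axis=1)


def er_transitivity_test(
    graph: nx.Graph,
    n_sim: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """One-tailed upper test of mean local transitivity against G(n, m).

    Degenerate when m = 0 or the graph is complete (every replicate is
    forced to the observed graph): p = 1 with a flag.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise GenotypeTableError("need >= 3 nodes for a transitivity test")
    m = graph.number_of_edges()
    t_obs, _ = mean_local_transitivity(graph)
    max_m = n * (n - 1) // 2
    if m == 0 or m == max_m:
        return TestResult(t_obs, 1.0, 0, "upper", seed, degenerate=True,
                          flags=["forced by edge count"])
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    batch = max(1, min(n_sim, 20_000_000 // (n * n) or 1))
    while done < n_sim:
        b = min(batch, n_sim - done)
        adj = sample_gnm_adjacency(n, m, b, rng)
        t_sim = _batch_mean_transitivity(adj)
        hits += int((t_sim >= t_obs - 1e-12).sum())
        done += b
    return TestResult(t_obs, (hits + 1) / (n_sim + 1), n_sim, "upper", seed)
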