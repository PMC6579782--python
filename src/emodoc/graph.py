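"""Weighted graph-theoretic properties of PLV networks.

PLV matrices stay fully weighted (no thresholding), so every metric uses
its weighted definition:

* clustering coefficient C — Onnela geometric-mean triangle intensity
  with weights normalized by the network maximum (delegated to networkx);
* characteristic path length L — Dijkstra shortest paths with edge length
  1/w, averaged over unordered node pairs;
* global efficiency Ge — mean inverse shortest-path length (0 for
  unreachable pairs), Latora-Marchiori;
* local efficiency Le — mean over nodes of the global efficiency of the
  subgraph induced by each node's neighbours;
* small-worldness sigma — (C/C_rand)/(L/L_rand) against degree-preserving
  rewired null graphs with the original weights shuffled onto the
  rewired edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .plv import PLVMatrix


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric non-negative weight matrix with zero diagonal."""

    weights: np.ndarray
    node_names: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if len(self.node_names) != w.shape[0]:
            raise ValueError("node_names must match weights")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("no self-loops: diagonal must be zero")
        if w.min() < 0:
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_plv(cls, m: PLVMatrix) -> "WeightedGraph":
        w = m.plv.copy()
        np.fill_diagonal(w, 0.0)  # the trivial self-locking is not an edge
        return cls(w, m.channel_names)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_names)
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    g.add_edge(self.node_names[i], self.node_names[j],
                               weight=self.weights[i, j])
        return g


@dataclass(frozen=True)
class GraphMetrics:
    C: float
    L: float
    Ge: float
    Le: float
    sigma: float | None = None


def _distance_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    return shortest_path(lengths, method="D", directed=False)


def clustering_coefficient(g: WeightedGraph) -> float:
    """Onnela weighted clustering, averaged over all nodes (isolated and
    degree-1 nodes contribute zero)."""
    if g.n_nodes < 3:
        raise ValueError("clustering needs at least 3 nodes")
    if not np.any(g.weights > 0):
        return 0.0
    return float(nx.average_clustering(g.to_networkx(), weight="weight", count_zeros=True))


def characteristic_path_length(g: WeightedGraph) -> float:
    """Mean 1/w shortest-path distance over unordered node pairs."""
    d = _distance_matrix(g.weights)
    iu = np.triu_indices(g.n_nodes, k=1)
    if np.isinf(d[iu]).any():
        raise ValueError(
            "graph is disconnected: characteristic path length is undefined; "
            "use global_efficiency, which treats unreachable pairs as 0"
        )
    return float(d[iu].mean())


def global_efficiency(g: WeightedGraph) -> float:
    """Mean inverse shortest-path distance; unreachable pairs count 0."""
    if g.n_nodes < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = _distance_matrix(g.weights)
    iu = np.triu_indices(g.n_nodes, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(d[iu] > 0, 1.0 / d[iu], 0.0)
    inv[np.isinf(d[iu])] = 0.0
    return float(inv.mean())


def local_efficiency(g: WeightedGraph) -> float:
    """Mean over nodes of the neighbourhood subgraph's global efficiency."""
    if g.n_nodes < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    effs = []
    for i in range(g.n_nodes):
        nbrs = np.flatnonzero(g.weights[i] > 0)
        if nbrs.size < 2:
            effs.append(0.0)
            continue
        sub = WeightedGraph(g.weights[np.ix_(nbrs, nbrs)],
                            tuple(g.node_names[j] for j in nbrs))
        effs.append(global_efficiency(sub))
    return float(np.mean(effs))


def node_strength(g: WeightedGraph) -> dict[str, float]:
    """Sum of edge weights per node (a descriptive hub indicator)."""
    s = g.weights.sum(axis=0)
    return {n: float(v) for n, v in zip(g.node_names, s)}


def _rewired_null(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    gx = g.to_networkx()
    m = gx.number_of_edges()
    null = gx.copy()
    if m >= 2:
        try:
            nx.double_edge_swap(null, nswap=m, max_tries=100 * m,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            # dense graphs (e.g. complete PLV networks) admit no swaps;
            # the degree-preserving null is then the same edge set
            null = gx.copy()
    idx = {n: i for i, n in enumerate(g.node_names)}
    weights = g.weights[np.triu_indices(g.n_nodes, k=1)]
    weights = rng.permutation(weights[weights > 0])
    w = np.zeros_like(g.weights)
    for (u, v), wt in zip(null.edges(), weights):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = wt
    return WeightedGraph(w, g.node_names)


def small_worldness(g: WeightedGraph, n_rand: int = 20, seed: int = 0) -> float:
    """sigma = (C/C_rand) / (L/L_rand) against rewired weight-shuffled nulls."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    c_obs = clustering_coefficient(g)
    l_obs = characteristic_path_length(g)  # raises if disconnected
    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    attempts = 0
    while len(c_rand) < n_rand:
        attempts += 1
        if attempts > 20 * n_rand:
            raise RuntimeError("degree-preserving rewiring kept disconnecting the graph")
        null = _rewired_null(g, rng)
        try:
            l_rand.append(characteristic_path_length(null))
        except ValueError:
            continue
        c_rand.append(clustering_coefficient(null))
    return float((c_obs / np.mean(c_rand)) / (l_obs / np.mean(l_rand)))


def network_metrics(
    g: WeightedGraph, with_sigma: bool = False, n_rand: int = 20, seed: int = 0
) -> GraphMetrics:
    return GraphMetrics(
        C=clustering_coefficient(g),
        L=characteristic_path_length(g),
        Ge=global_efficiency(g),
        Le=local_efficiency(g),
        sigma=small_worldness(g, n_rand, seed) if with_sigma else None,
    )
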