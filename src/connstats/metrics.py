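"""Weighted graph-theoretic metrics for connectomes.

Conventions (stated because the field varies):

* **Lengths.** Shortest-path metrics run on the reciprocal-weight length
  graph (``length = 1 / weight``): strong connections are short.  This is
  the standard mapping for streamline-count networks and is isolated in
  :func:`weight_to_length` so it can be swapped.
* **Clustering.** Onnela-type weighted clustering: geometric mean of
  triangle weights, with weights normalized by the global maximum.  On
  binary graphs this reduces to the triangle fraction.
* **Disconnected pairs** are excluded from the characteristic path length
  (the count is reported) and contribute zero to global efficiency, which
  is the measure meant to tolerate them.
* **Rich club.** The weighted coefficient evaluated at binary-degree
  thresholds k: the total weight among nodes of degree > k over the sum of
  the same number of globally strongest edge weights; undefined (NaN) when
  fewer than two nodes survive.
* **Modularity** is maximized with seeded multi-level (Louvain) restarts,
  keeping the best weighted Q.

All per-node metrics are returned in node order.  Betweenness is normalized
by (n-1)(n-2)/2, so a star center scores exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectome import ConnectomeMatrix

__all__ = [
    "GraphMetricProfile",
    "strength_and_degree",
    "weight_to_length",
    "path_metrics",
    "local_efficiency",
    "clustering_weighted",
    "betweenness",
    "modularity_louvain",
    "rich_club_curve",
    "small_worldness",
    "compute_profile",
]


def _as_weights(g) -> np.ndarray:
    if isinstance(g, ConnectomeMatrix):
        return g.weights
    return np.asarray(g, dtype=float)


def strength_and_degree(g):
    """Node strength (sum of incident weights) and binary degree."""
    w = _as_weights(g)
    return w.sum(axis=1), (w > 0).sum(axis=1)


def weight_to_length(g) -> np.ndarray:
    """Reciprocal map to the length graph: 1/w for w > 0, inf for absent edges."""
    w = _as_weights(g)
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(length, 0.0)
    return length


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    iu, ju = np.nonzero(np.triu(w, 1))
    lengths = 1.0 / w[iu, ju]
    graph = csr_matrix((lengths, (iu, ju)), shape=(n, n))
    return shortest_path(graph, method="D", directed=False)


def path_metrics(g):
    """All-pairs distances plus characteristic path length and global efficiency.

    Returns
    -------
    D : (n, n) distance matrix on the length graph (inf for disconnected).
    L : mean finite off-diagonal distance.
    E : mean inverse distance (1/inf = 0), i.e. global efficiency.
    """
    w = _as_weights(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    D = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    if not finite.any():
        raise ValueError("fully disconnected graph: path length undefined")
    L = float(D[finite].mean())
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    E = float(inv[off].mean())
    return D, L, E


def global_efficiency(g) -> float:
    """Mean inverse shortest path length (0 for an edgeless graph)."""
    w = _as_weights(g)
    n = w.shape[0]
    if n < 2:
        return 0.0
    D = _distance_matrix(w)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    return float(inv[off].mean())


def local_efficiency(g) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph.

    The node itself is excluded; nodes of degree < 2 score 0.
    """
    w = _as_weights(g)
    n = w.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        eff[i] = global_efficiency(w[np.ix_(nbrs, nbrs)])
    return eff


def clustering_weighted(g) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With weights scaled by the global maximum,
    ``C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w_ij w_ih w_jh)^(1/3)``.
    Binary graphs reduce to the fraction of closed triangles; degree < 2
    gives 0.
    """
    w = _as_weights(g)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0])
    w_hat = (w / wmax) ** (1.0 / 3.0)
    cyc3 = np.diag(w_hat @ w_hat @ w_hat)
    k = (w > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, cyc3 / denom, 0.0)
    return c


def _as_length_graph(w: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(w.shape[0]))
    iu, ju = np.nonzero(np.triu(w, 1))
    G.add_weighted_edges_from(
        ((int(a), int(b), 1.0 / w[a, b]) for a, b in zip(iu, ju)),
        weight="length",
    )
    return G


def betweenness(g) -> np.ndarray:
    """Shortest-path betweenness centrality on the length graph.

    Equal-length path multiplicities are counted (Brandes); values are
    normalized by (n-1)(n-2)/2 so they live in [0, 1].
    """
    w = _as_weights(g)
    G = _as_length_graph(w)
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return np.array([bc[i] for i in range(w.shape[0])])


def modularity_louvain(g, gamma: float = 1.0, n_repeats: int = 100, seed: int = 0):
    """Weighted modularity maximization with seeded Louvain restarts.

    The best Q over ``n_repeats`` restarts is kept (ties: first found).
    Returns ``(partition, Q)`` where partition is a list of node sets.
    """
    w = _as_weights(g)
    if not (w > 0).any():
        raise ValueError("edgeless graph has no modular structure")
    G = nx.Graph()
    G.add_nodes_from(range(w.shape[0]))
    iu, ju = np.nonzero(np.triu(w, 1))
    G.add_weighted_edges_from(
        (int(a), int(b), float(w[a, b])) for a, b in zip(iu, ju)
    )
    best_q, best_part = -np.inf, None
    for rep in range(n_repeats):
        part = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=seed + rep
        )
        q = nx.community.modularity(G, part, weight="weight", resolution=gamma)
        if q > best_q:
            best_q, best_part = q, part
    return [set(c) for c in best_part], float(best_q)


def rich_club_curve(g, k_values=None) -> dict:
    """Weighted rich-club coefficient phi(k) over binary-degree thresholds.

    ``phi(k) = W_{>k} / sum of the E_{>k} strongest edge weights``, where
    ``W_{>k}`` and ``E_{>k}`` are the total weight and edge count among
    nodes of degree > k.  NaN where fewer than 2 nodes survive; 0 when they
    survive but share no edge.
    """
    w = _as_weights(g)
    strength, degree = strength_and_degree(w)
    iu, ju = np.nonzero(np.triu(w, 1))
    all_weights = np.sort(w[iu, ju])[::-1]
    if k_values is None:
        kmax = int(degree.max()) if degree.size else 0
        k_values = range(1, kmax)
    phi = {}
    for k in k_values:
        nodes = np.flatnonzero(degree > k)
        if nodes.size < 2:
            phi[int(k)] = float("nan")
            continue
        sub = w[np.ix_(nodes, nodes)]
        iu_s, ju_s = np.nonzero(np.triu(sub, 1))
        e_k = iu_s.size
        if e_k == 0:
            phi[int(k)] = 0.0
            continue
        w_k = sub[iu_s, ju_s].sum()
        phi[int(k)] = float(w_k / all_weights[:e_k].sum())
    return phi


def small_worldness(c_norm: float, l_norm: float) -> float:
    """sigma = normalized clustering / normalized path length."""
    if l_norm <= 0:
        raise ValueError("normalized path length must be positive")
    return c_norm / l_norm


@dataclass
class GraphMetricProfile:
    """All metrics of one network: per-node vectors and global scalars.

    Normalized fields are quotients against a degree-, weight- and
    strength-preserving null ensemble and stay None until filled by
    :func:`connstats.nulls.normalize_profile`.
    """

    strength: np.ndarray
    degree: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    mean_strength: float
    characteristic_path_length: float
    global_efficiency: float
    mean_clustering: float
    modularity: float
    partition: list
    rich_club: dict
    n_disconnected_pairs: int = 0
    normalized: dict = field(default_factory=dict)
    small_worldness: float = None

    def global_metrics(self) -> dict:
        return {
            "mean_strength": self.mean_strength,
            "characteristic_path_length": self.characteristic_path_length,
            "global_efficiency": self.global_efficiency,
            "mean_clustering": self.mean_clustering,
            "modularity": self.modularity,
        }


def compute_profile(
    g,
    gamma: float = 1.0,
    louvain_repeats: int = 100,
    seed: int = 0,
    k_values=None,
    include_betweenness: bool = True,
    include_local_efficiency: bool = True,
) -> GraphMetricProfile:
    """Compute the full metric profile of one network.

    ``include_*`` flags skip the two most expensive per-node metrics when a
    profile is only needed for global null normalization.
    """
    w = _as_weights(g)
    n = w.shape[0]
    strength, degree = strength_and_degree(w)
    D, L, E = path_metrics(w)
    off = ~np.eye(n, dtype=bool)
    n_disc = int((~np.isfinite(D) & off).sum() // 2)
    clustering = clustering_weighted(w)
    part, q = modularity_louvain(w, gamma=gamma, n_repeats=louvain_repeats, seed=seed)
    return GraphMetricProfile(
        strength=strength,
        degree=degree,
        betweenness=betweenness(w) if include_betweenness else None,
        clustering=clustering,
        local_efficiency=local_efficiency(w) if include_local_efficiency else None,
        mean_strength=float(strength.mean()),
        characteristic_path_length=L,
        global_efficiency=E,
        mean_clustering=float(clustering.mean()),
        modularity=q,
        partition=part,
        rich_club=rich_club_curve(w, k_values),
        n_disconnected_pairs=n_disc,
    )
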