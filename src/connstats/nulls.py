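"""Degree-, weight- and strength-preserving random networks.

Normalized graph metrics (clustering, path length, efficiency, modularity,
small-worldness, rich club) are quotients against an ensemble of randomized
networks that keep the original degree sequence and weight multiset exactly
and the per-node strengths approximately.  Construction is two-stage:

1. :func:`rewire_preserving_degree` — connected double-edge swaps randomize
   the topology while preserving every node's binary degree;
2. :func:`reassign_weights_strength_preserving` — the original weight
   multiset is placed onto the new topology by greedy rank-matching: the
   largest remaining weight goes to the free edge with the largest product
   of residual target strengths, and the residuals are decremented as
   weights are placed.  This keeps node strengths close to the original
   (the error is reported, not assumed).

Normalization always divides by the ensemble *mean*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .connectome import ConnectomeMatrix
from .metrics import GraphMetricProfile, compute_profile, small_worldness

__all__ = [
    "NullEnsemble",
    "rewire_preserving_degree",
    "reassign_weights_strength_preserving",
    "null_ensemble",
    "normalize_by_null",
    "normalize_profile",
    "normalized_rich_club",
    "strength_preservation_error",
]


def rewire_preserving_degree(
    g: ConnectomeMatrix, swaps_per_edge: int = 10, seed: int = 0
) -> ConnectomeMatrix:
    """Randomize topology by double-edge swaps; degrees preserved exactly.

    Returns a unit-weight matrix carrying only the rewired topology.  Graphs
    with no legal swap (complete, or fewer than two independent edges) come
    back unchanged with a warning.  ``swaps_per_edge * n_edges`` swap
    attempts give well-mixed topologies for connectome-like densities.
    """
    w = g.weights
    n = g.n_nodes
    iu, ju = np.nonzero(np.triu(w, 1))
    m = iu.size
    binary = np.zeros((n, n))
    binary[iu, ju] = 1.0
    binary += binary.T
    if m < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire")
        return ConnectomeMatrix(binary, list(g.labels))
    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(iu.tolist(), ju.tolist()))
    nswap = swaps_per_edge * m
    try:
        nx.double_edge_swap(G, nswap=nswap, max_tries=100 * nswap, seed=int(seed))
    except nx.NetworkXException as exc:
        warnings.warn(f"degree-preserving rewire impossible ({exc}); returning copy")
        return ConnectomeMatrix(binary, list(g.labels))
    out = np.zeros((n, n))
    for a, b in G.edges:
        out[a, b] = out[b, a] = 1.0
    return ConnectomeMatrix(out, list(g.labels))


def reassign_weights_strength_preserving(
    topology: ConnectomeMatrix, original: ConnectomeMatrix, seed: int = 0
) -> ConnectomeMatrix:
    """Place the original weight multiset onto a rewired topology.

    Greedy descending assignment: at each step the largest unplaced weight
    goes to the free edge whose endpoints have the largest product of
    residual target strengths; the residuals are then decremented by the
    placed weight.  The weight multiset is preserved exactly, per-node
    strength approximately.  ``seed`` jitters tie-breaking among equal-score
    edges.
    """
    iu, ju = np.nonzero(np.triu(topology.weights, 1))
    oi, oj = np.nonzero(np.triu(original.weights, 1))
    if iu.size != oi.size:
        raise ValueError(
            f"topology has {iu.size} edges but original has {oi.size}"
        )
    weights = np.sort(original.weights[oi, oj])[::-1]
    target = original.weights.sum(axis=1).astype(float)
    rng = np.random.default_rng(seed)
    resid = target.copy()
    m = iu.size
    avail = np.ones(m, dtype=bool)
    # tiny multiplicative jitter: random tie-breaks without reordering
    # meaningfully different scores
    jitter = 1.0 + 1e-12 * rng.random(m)
    out = np.zeros_like(original.weights)
    for w in weights:
        scores = resid[iu] * resid[ju] * jitter
        scores[~avail] = -np.inf
        k = int(np.argmax(scores))
        a, b = iu[k], ju[k]
        out[a, b] = out[b, a] = w
        resid[a] -= w
        resid[b] -= w
        avail[k] = False
    return ConnectomeMatrix(out, list(original.labels))


def strength_preservation_error(original: ConnectomeMatrix, null: ConnectomeMatrix) -> float:
    """Mean relative per-node strength error of a null member."""
    s0 = original.weights.sum(axis=1)
    s1 = null.weights.sum(axis=1)
    nz = s0 > 0
    return float(np.mean(np.abs(s1[nz] - s0[nz]) / s0[nz]))


@dataclass
class NullEnsemble:
    """A seeded ensemble of randomized networks with their metric profiles."""

    source_n_nodes: int
    n_networks: int
    members: list
    profiles: list
    seed: int
    mean_strength_error: float = None
    extras: dict = field(default_factory=dict)

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(p, name) for p in self.profiles])


def null_ensemble(
    g: ConnectomeMatrix,
    n: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    gamma: float = 1.0,
    louvain_repeats: int = 10,
    k_values=None,
    compute_profiles: bool = True,
) -> NullEnsemble:
    """Generate ``n`` independent null networks (deterministic given seed).

    Profiles omit betweenness and local efficiency — local metrics are
    reported raw, so nulls only need the global metrics and rich-club
    curves used for normalization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed).spawn(n)
    members, profiles, errs = [], [], []
    for i in range(n):
        s1, s2 = (int(x) for x in ss[i].generate_state(2) % (2**31))
        topo = rewire_preserving_degree(g, swaps_per_edge=swaps_per_edge, seed=s1)
        member = reassign_weights_strength_preserving(topo, g, seed=s2)
        members.append(member)
        errs.append(strength_preservation_error(g, member))
        if compute_profiles:
            profiles.append(
                compute_profile(
                    member,
                    gamma=gamma,
                    louvain_repeats=louvain_repeats,
                    seed=s2,
                    k_values=k_values,
                    include_betweenness=False,
                    include_local_efficiency=False,
                )
            )
    return NullEnsemble(
        source_n_nodes=g.n_nodes,
        n_networks=n,
        members=members,
        profiles=profiles,
        seed=seed,
        mean_strength_error=float(np.mean(errs)),
    )


def normalize_by_null(value: float, ensemble_values) -> float:
    """value / mean(ensemble values); errors on a zero ensemble mean."""
    vals = np.asarray(ensemble_values, dtype=float)
    mean = vals.mean()
    if mean == 0 or not np.isfinite(mean):
        raise ValueError("ensemble mean is zero or non-finite")
    return float(value / mean)


def normalized_rich_club(profile_or_graph, ensemble: NullEnsemble) -> dict:
    """phi_norm(k) = phi(k) / mean phi_null(k); undefined k stays NaN."""
    if isinstance(profile_or_graph, GraphMetricProfile):
        phi = profile_or_graph.rich_club
    else:
        from .metrics import rich_club_curve

        phi = rich_club_curve(profile_or_graph)
    out = {}
    for k, v in phi.items():
        member_vals = np.array(
            [p.rich_club.get(k, np.nan) for p in ensemble.profiles]
        )
        if not np.isfinite(v) or not np.isfinite(member_vals).all():
            out[k] = float("nan")
            continue
        mean = member_vals.mean()
        out[k] = float(v / mean) if mean > 0 else float("nan")
    return out


def normalize_profile(profile: GraphMetricProfile, ensemble: NullEnsemble) -> GraphMetricProfile:
    """Fill a profile's normalized global metrics from a null ensemble.

    Adds normalized clustering / path length / efficiency / modularity /
    strength, the normalized rich-club curve, and small-worldness
    (normalized clustering over normalized path length).
    """
    for name in (
        "mean_clustering",
        "characteristic_path_length",
        "global_efficiency",
        "modularity",
        "mean_strength",
    ):
        profile.normalized[name] = normalize_by_null(
            getattr(profile, name), ensemble.metric_values(name)
        )
    profile.normalized["rich_club"] = normalized_rich_club(profile, ensemble)
    profile.small_worldness = small_worldness(
        profile.normalized["mean_clustering"],
        profile.normalized["characteristic_path_length"],
    )
    return profile
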