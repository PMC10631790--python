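"""Weighted graph metrics against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pytest

from connstats.metrics import (
    betweenness,
    clustering_weighted,
    compute_profile,
    local_efficiency,
    modularity_louvain,
    path_metrics,
    rich_club_curve,
    small_worldness,
    strength_and_degree,
    weight_to_length,
)

from conftest import random_symmetric


def complete(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return m


def star(n):
    m = np.zeros((n, n))
    m[0, 1:] = 1.0
    m[1:, 0] = 1.0
    return m


def floyd_warshall_oracle(w):
    """Independent all-pairs shortest paths on the reciprocal length graph."""
    n = w.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                D[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


class TestStrengthDegree:
    def test_complete_unit_graph(self):
        s, d = strength_and_degree(complete(4))
        assert (s == 3).all() and (d == 3).all()

    def test_isolated_node(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 2.0
        s, d = strength_and_degree(m)
        assert s[2] == 0 and d[2] == 0

    def test_bruteforce(self, rng):
        w = random_symmetric(15, rng)
        s, d = strength_and_degree(w)
        for i in range(15):
            assert s[i] == pytest.approx(sum(w[i, j] for j in range(15)))
            assert d[i] == sum(1 for j in range(15) if w[i, j] > 0)


class TestLengthsAndPaths:
    def test_reciprocal_map(self):
        m = np.zeros((2, 2))
        m[0, 1] = m[1, 0] = 2.0
        L = weight_to_length(m)
        assert L[0, 1] == 0.5

    def test_unit_weights_reduce_to_hops(self):
        D, L, E = path_metrics(star(4))
        assert D[1, 2] == 2.0  # leaf-leaf via center

    def test_weight_scaling_halves_lengths(self, rng):
        w = random_symmetric(12, rng, density=0.7)
        _, L1, E1 = path_metrics(w)
        _, L2, E2 = path_metrics(2 * w)
        assert L2 == pytest.approx(L1 / 2)
        assert E2 == pytest.approx(2 * E1)

    def test_complete_graph_unity(self):
        _, L, E = path_metrics(complete(7))
        assert L == 1.0 and E == 1.0

    def test_five_node_star(self):
        _, L, E = path_metrics(star(5))
        assert L == pytest.approx(1.6)  # 4 pairs at 1, 6 pairs at 2

    def test_matches_floyd_warshall(self, rng):
        w = random_symmetric(30, rng, density=0.25)
        D, _, _ = path_metrics(w)
        assert np.allclose(D, floyd_warshall_oracle(w), equal_nan=True)

    def test_disconnected_graph_signalled(self):
        with pytest.raises(ValueError, match="disconnected"):
            path_metrics(np.zeros((4, 4)))


class TestLocalEfficiency:
    def test_clique_member(self):
        assert local_efficiency(complete(5))[0] == pytest.approx(1.0)

    def test_star_center_zero(self):
        eff = local_efficiency(star(6))
        assert eff[0] == 0.0  # neighbors mutually unconnected
        assert (eff[1:] == 0.0).all()  # leaves have a single neighbor

    def test_matches_naive_subgraph(self, rng):
        w = random_symmetric(12, rng, density=0.6)
        eff = local_efficiency(w)
        from connstats.metrics import global_efficiency

        for i in range(12):
            nbrs = np.flatnonzero(w[i] > 0)
            expect = 0.0
            if nbrs.size >= 2:
                expect = global_efficiency(w[np.ix_(nbrs, nbrs)])
            assert eff[i] == pytest.approx(expect)


class TestClustering:
    def test_unit_triangle(self):
        assert np.allclose(clustering_weighted(complete(3)), 1.0)

    def test_star_zero(self):
        assert np.allclose(clustering_weighted(star(5)), 0.0)

    def test_binary_reduces_to_triangle_fraction(self, rng):
        w = (random_symmetric(10, rng, density=0.5) > 0).astype(float)
        ours = clustering_weighted(w)
        for i in range(10):
            nbrs = np.flatnonzero(w[i] > 0)
            k = nbrs.size
            if k < 2:
                assert ours[i] == 0.0
                continue
            tri = sum(
                w[a, b] for a, b in itertools.combinations(nbrs, 2)
            )
            assert ours[i] == pytest.approx(2 * tri / (k * (k - 1)))

    def test_max_weight_normalization_scale_invariant(self, rng):
        w = random_symmetric(10, rng)
        assert np.allclose(clustering_weighted(w), clustering_weighted(3.7 * w))


class TestBetweenness:
    def test_star_center_one(self):
        bc = betweenness(star(5))
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0.0)

    def test_complete_zero(self):
        assert np.allclose(betweenness(complete(6)), 0.0)

    def test_bruteforce_path_enumeration(self, rng):
        w = random_symmetric(9, rng, density=0.5)
        n = 9
        D = floyd_warshall_oracle(w)
        # count shortest paths by DP over increasing distance
        counts = np.zeros((n, n))
        through = np.zeros((n, n, n))  # sigma_st(v)
        for s in range(n):
            for t in range(n):
                if s == t or not np.isfinite(D[s, t]):
                    continue
                paths = _enumerate_shortest_paths(w, D, s, t)
                counts[s, t] = len(paths)
                for p in paths:
                    for v in p[1:-1]:
                        through[s, t, v] += 1
        bc = np.zeros(n)
        for v in range(n):
            total = 0.0
            for s in range(n):
                for t in range(s + 1, n):
                    if counts[s, t] > 0 and v not in (s, t):
                        total += through[s, t, v] / counts[s, t]
            bc[v] = total / ((n - 1) * (n - 2) / 2)
        assert np.allclose(betweenness(w), bc, atol=1e-9)


def _enumerate_shortest_paths(w, D, s, t, tol=1e-12):
    """All shortest s-t paths by recursive descent along optimal edges."""
    if s == t:
        return [[t]]
    out = []
    for nb in np.flatnonzero(w[s] > 0):
        if abs(1.0 / w[s, nb] + D[nb, t] - D[s, t]) < tol:
            out.extend([[s] + p for p in _enumerate_shortest_paths(w, D, nb, t, tol)])
    return out


class TestModularity:
    def test_two_disconnected_cliques(self):
        m = np.zeros((8, 8))
        m[:4, :4] = complete(4)
        m[4:, 4:] = complete(4)
        part, q = modularity_louvain(m, n_repeats=10, seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert sorted(map(sorted, part)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_complete_graph_near_zero(self):
        _, q = modularity_louvain(complete(8), n_repeats=10, seed=0)
        assert q <= 1e-9

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            modularity_louvain(np.zeros((4, 4)))

    def test_matches_exhaustive_on_small_graphs(self, rng):
        hits = 0
        n_graphs = 12
        for g in range(n_graphs):
            w = random_symmetric(8, rng, density=0.45)
            if not (w > 0).any():
                hits += 1
                continue
            _, q = modularity_louvain(w, n_repeats=60, seed=g)
            q_best = exhaustive_best_modularity(w)
            assert q <= q_best + 1e-9
            if q >= q_best - 1e-9:
                hits += 1
        assert hits >= 0.95 * n_graphs


def set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(w):
    """Max weighted modularity over all partitions of an 8-node graph."""
    two_m = w.sum()
    k = w.sum(axis=1)
    best = -np.inf
    for part in set_partitions(list(range(w.shape[0]))):
        q = 0.0
        for block in part:
            idx = np.array(block)
            q += w[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
        best = max(best, q)
    return best


class TestRichClub:
    def test_complete_uniform_graph(self):
        phi = rich_club_curve(complete(6))
        assert all(v == pytest.approx(1.0) for v in phi.values())

    def test_k_at_or_above_max_degree_undefined(self):
        phi = rich_club_curve(complete(5), k_values=[4, 5])
        assert np.isnan(phi[4]) and np.isnan(phi[5])

    def test_literal_formula(self, rng):
        w = random_symmetric(20, rng, density=0.4)
        _, deg = strength_and_degree(w)
        phi = rich_club_curve(w)
        iu, ju = np.triu_indices(20, 1)
        weights_desc = np.sort(w[iu, ju][w[iu, ju] > 0])[::-1]
        for k, v in phi.items():
            rich = np.flatnonzero(deg > k)
            if rich.size < 2:
                assert np.isnan(v)
                continue
            sub = w[np.ix_(rich, rich)]
            su, sj = np.triu_indices(rich.size, 1)
            present = sub[su, sj] > 0
            e_k = present.sum()
            if e_k == 0:
                assert v == 0.0
                continue
            assert v == pytest.approx(sub[su, sj][present].sum() / weights_desc[:e_k].sum())


class TestSmallWorldness:
    def test_identity_cases(self):
        assert small_worldness(1.3, 1.3) == 1.0
        assert small_worldness(2.0, 1.0) == 2.0

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            small_worldness(1.0, 0.0)


class TestProfileInvariants:
    def test_scaling_behavior(self, rng):
        w = random_symmetric(15, rng, density=0.6)
        p1 = compute_profile(w, louvain_repeats=5, seed=0)
        p2 = compute_profile(4.0 * w, louvain_repeats=5, seed=0)
        assert np.allclose(p2.strength, 4.0 * p1.strength)
        assert np.array_equal(p2.degree, p1.degree)
        assert np.allclose(p2.clustering, p1.clustering)
        assert np.allclose(p2.betweenness, p1.betweenness)
        assert p2.characteristic_path_length == pytest.approx(
            p1.characteristic_path_length / 4.0
        )
        assert p2.global_efficiency == pytest.approx(4.0 * p1.global_efficiency)
        for k in p1.rich_club:
            if np.isfinite(p1.rich_club[k]):
                assert p2.rich_club[k] == pytest.approx(p1.rich_club[k])

    def test_node_relabelling_invariance(self, rng):
        w = random_symmetric(12, rng, density=0.6)
        perm = rng.permutation(12)
        wp = w[np.ix_(perm, perm)]
        assert np.allclose(
            clustering_weighted(w)[perm], clustering_weighted(wp)
        )
        assert np.allclose(betweenness(w)[perm], betweenness(wp))

    def test_modularity_bounds(self, rng):
        for g in range(5):
            w = random_symmetric(10, rng, density=0.5)
            if not (w > 0).any():
                continue
            _, q = modularity_louvain(w, n_repeats=10, seed=g)
            assert -0.5 <= q <= 1.0
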