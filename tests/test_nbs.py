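"""Network-based statistic: edge stats, components, permutation p values."""

import networkx as nx
import numpy as np
import pytest

from connstats.connectome import group_threshold
from connstats.nbs import (
    NBS,
    EdgeStatMap,
    NBSConfig,
    component_size,
    edgewise_statistics,
    exhaustive_nbs_test,
    extract_components,
    nbs_test,
    network_mean_connectivity,
)
from connstats.stats import t_test
from connstats.synthetic import SyntheticConfig, generate_cohort, recovery_score

from conftest import make_cohort, random_symmetric


def stat_map_from_matrix(stats_matrix):
    n = stats_matrix.shape[0]
    iu, ju = np.triu_indices(n, 1)
    return EdgeStatMap(
        stats=stats_matrix[iu, ju], iu=iu, ju=ju, n_nodes=n,
        df=10, design="group_difference", direction="group1_less",
    )


class TestEdgewiseStatistics:
    def test_identical_groups_all_zero(self, rng):
        base = random_symmetric(6, rng)
        cohort = make_cohort([base.copy() for _ in range(6)], ["A"] * 3 + ["B"] * 3)
        sm = edgewise_statistics(cohort, NBSConfig())
        assert np.allclose(sm.stats, 0.0)
        assert sm.flagged.all()

    def test_edge_t_matches_t_test(self, toy_cohort):
        sm = edgewise_statistics(toy_cohort, NBSConfig())
        X, iu, ju = toy_cohort.edge_data_matrix()
        k = 3  # arbitrary masked edge
        res = t_test(X[:3, k], X[3:, k], variant="pooled")
        assert sm.stats[k] == pytest.approx(res.statistic, rel=1e-10)

    def test_direction_flips_sign(self, toy_cohort):
        lo = edgewise_statistics(toy_cohort, NBSConfig(direction="group1_less"))
        hi = edgewise_statistics(toy_cohort, NBSConfig(direction="group1_greater"))
        assert np.allclose(lo.stats, -hi.stats)

    def test_correlation_design_matches_r_to_t(self, rng):
        mats = [random_symmetric(5, rng, density=1.0) for _ in range(10)]
        behavior = {"commission_errors": rng.normal(10, 3, 10)}
        cohort = make_cohort(mats, ["A"] * 5 + ["B"] * 5, behavior)
        cfg = NBSConfig(design="correlation", direction="positive")
        sm = edgewise_statistics(cohort, cfg, behavior="commission_errors")
        X, iu, ju = cohort.edge_data_matrix()
        from connstats.stats import correlate

        k = 2
        ref = correlate(X[:, k], np.asarray(cohort.behavior["commission_errors"]))
        assert sm.stats[k] == pytest.approx(ref.statistic, rel=1e-9)

    def test_degenerate_perfect_correlation_flagged(self, rng):
        mats = [random_symmetric(4, rng, density=1.0) for _ in range(8)]
        X = np.array([m[0, 1] for m in mats])
        cohort = make_cohort(mats, ["A"] * 4 + ["B"] * 4, {"inattention": X})
        cfg = NBSConfig(design="correlation", direction="positive")
        sm = edgewise_statistics(cohort, cfg, behavior="inattention")
        k = np.flatnonzero((sm.iu == 0) & (sm.ju == 1))[0]
        assert sm.flagged[k]
        assert np.isfinite(sm.stats[k])  # capped, not infinite

    def test_constant_behavior_rejected(self, rng):
        mats = [random_symmetric(4, rng) for _ in range(6)]
        cohort = make_cohort(mats, ["A"] * 3 + ["B"] * 3,
                             {"inattention": [5.0] * 6})
        with pytest.raises(ValueError, match="constant"):
            edgewise_statistics(
                cohort, NBSConfig(design="correlation", direction="negative"),
                behavior="inattention",
            )


class TestComponents:
    def test_toy_partition(self):
        m = np.zeros((6, 6))
        for (a, b) in [(0, 1), (1, 2), (3, 4)]:
            m[a, b] = m[b, a] = 5.0
        comps = extract_components(stat_map_from_matrix(m), 3.0, primary="extent")
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].nodes == frozenset({0, 1, 2})

    def test_threshold_above_max_empty(self):
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 2.9
        assert extract_components(stat_map_from_matrix(m), 3.0) == []

    def test_matches_networkx_components(self, rng):
        for _ in range(20):
            m = np.triu(rng.normal(0, 2, (50, 50)), 1)
            m = m + m.T
            comps = extract_components(stat_map_from_matrix(m), 1.5)
            G = nx.Graph((tuple(e) for c in comps for e in c.edges))
            expected = nx.Graph()
            iu, ju = np.nonzero(np.triu(m, 1) > 1.5)
            expected.add_edges_from(zip(iu.tolist(), ju.tolist()))
            ours = {frozenset(c.nodes) for c in comps}
            ref = {frozenset(cc) for cc in nx.connected_components(expected)}
            assert ours == ref

    def test_component_size_measures(self):
        m = np.zeros((4, 4))
        for (a, b), s in zip([(0, 1), (1, 2), (2, 3)], (3.2, 3.5, 4.1)):
            m[a, b] = m[b, a] = s
        (comp,) = extract_components(stat_map_from_matrix(m), 3.0)
        assert component_size(comp, "extent") == 3
        assert component_size(comp, "intensity") == pytest.approx(10.8)

    def test_intensity_excess_variant(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 3.5
        (comp,) = extract_components(
            stat_map_from_matrix(m), 3.0, intensity_excess=True
        )
        assert comp.intensity == pytest.approx(0.5)

    def test_threshold_monotonicity(self, rng):
        m = np.triu(rng.normal(1, 1.5, (30, 30)), 1)
        m = m + m.T
        sm = stat_map_from_matrix(m)
        lo = extract_components(sm, 1.0)
        hi = extract_components(sm, 2.0)
        lo_edges = {e for c in lo for e in c.edges}
        hi_edges = {e for c in hi for e in c.edges}
        assert hi_edges <= lo_edges
        assert max((c.extent for c in hi), default=0) <= max(
            (c.extent for c in lo), default=0
        )

    def test_node_relabelling_equivariance(self, rng):
        m = np.triu(rng.normal(1, 1.5, (12, 12)), 1)
        m = m + m.T
        perm = rng.permutation(12)
        mp = m[np.ix_(perm, perm)]
        orig = extract_components(stat_map_from_matrix(m), 1.5)
        relab = extract_components(stat_map_from_matrix(mp), 1.5)
        mapped = {
            frozenset(int(np.flatnonzero(perm == n)[0]) for n in c.nodes)
            for c in orig
        }
        assert {frozenset(c.nodes) for c in relab} == mapped


class TestPermutationTest:
    def test_planted_network_recovery(self):
        cfg = SyntheticConfig(n_nodes=60, n_per_group=(20, 20), effect_delta=0.5,
                              planted_n_nodes=10, planted_n_edges=15, seed=31)
        cohort, truth = generate_cohort(cfg)
        cohort = group_threshold(cohort)
        res = NBS(cohort, thresholds=[3.0]).fit(n_permutations=1000, seed=1)
        comps = res.significant_components(0.05)
        assert comps
        assert recovery_score(set(comps[0].edges), truth) >= 0.8

    def test_deterministic_given_seed(self, toy_cohort):
        a = NBS(toy_cohort, thresholds=[2.0]).fit(n_permutations=200, seed=4)
        b = NBS(toy_cohort, thresholds=[2.0]).fit(n_permutations=200, seed=4)
        assert np.array_equal(
            a.null_max_sizes[2.0]["intensity"], b.null_max_sizes[2.0]["intensity"]
        )
        assert [c.p_fwe for c in a.components[2.0]] == [
            c.p_fwe for c in b.components[2.0]
        ]

    def test_p_nonincreasing_in_size(self, rng):
        cfg = SyntheticConfig(n_nodes=40, n_per_group=(10, 10), effect_delta=0.3,
                              planted_n_nodes=8, planted_n_edges=12, seed=41)
        cohort, _ = generate_cohort(cfg)
        cohort = group_threshold(cohort)
        res = NBS(cohort, thresholds=[2.0]).fit(n_permutations=300, seed=2)
        comps = sorted(res.components[2.0], key=lambda c: c.intensity)
        ps = [c.p_fwe_intensity for c in comps]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_both_measures_same_components(self, toy_cohort):
        ext = NBS(toy_cohort, thresholds=[2.0], size_measure="extent").fit(100, seed=3)
        inten = NBS(toy_cohort, thresholds=[2.0], size_measure="intensity").fit(100, seed=3)
        assert [c.edges for c in ext.components[2.0]] == [
            c.edges for c in inten.components[2.0]
        ]

    def test_low_permutation_warning(self, toy_cohort):
        res = NBS(toy_cohort, thresholds=[2.0]).fit(n_permutations=10, seed=0)
        assert res.warnings

    def test_summary_renders(self, toy_cohort):
        res = NBS(toy_cohort, thresholds=[2.0, 3.0]).fit(n_permutations=100, seed=0)
        text = res.summary()
        assert "Network-based statistic" in text
        assert "permutations: 100" in text


class TestExhaustiveOracle:
    def _small_cohort(self, seed, n1=3, n2=3):
        cfg = SyntheticConfig(n_nodes=12, n_per_group=(n1, n2), effect_delta=0.6,
                              connection_density=0.6, planted_n_nodes=4,
                              planted_n_edges=4, seed=seed)
        cohort, _ = generate_cohort(cfg)
        return group_threshold(cohort, 0.0)

    def test_three_vs_three_enumeration(self):
        cohort = self._small_cohort(5)
        res = exhaustive_nbs_test(cohort, NBSConfig(thresholds=(2.0,)))
        assert res.n_permutations == 20  # C(6, 3)
        assert res.exhaustive

    def test_observed_labelling_counted_once(self):
        cohort = self._small_cohort(5)
        res = exhaustive_nbs_test(cohort, NBSConfig(thresholds=(2.0,)))
        for c in res.components[2.0]:
            assert c.p_fwe >= 1 / 20  # the observed assignment itself

    def test_monte_carlo_matches_exhaustive(self):
        cohort = self._small_cohort(8, 4, 4)  # C(8,4) = 70 assignments
        cfg = NBSConfig(thresholds=(2.0,), n_permutations=14000, seed=11)
        ex = exhaustive_nbs_test(cohort, cfg)
        mc = nbs_test(cohort, cfg)
        for a, b in zip(ex.components[2.0], mc.components[2.0]):
            se = np.sqrt(a.p_fwe * (1 - a.p_fwe) / cfg.n_permutations)
            assert abs(a.p_fwe - b.p_fwe) <= 3 * se + 1e-3

    def test_degenerate_identical_subjects(self, rng):
        base = random_symmetric(6, rng)
        cohort = make_cohort([base.copy() for _ in range(6)], ["A"] * 3 + ["B"] * 3)
        res = exhaustive_nbs_test(cohort, NBSConfig(thresholds=(3.0,)))
        assert res.components[3.0] == []
        assert (res.null_max_sizes[3.0]["extent"] == 0).all()

    def test_infeasible_size_rejected(self, rng):
        mats = [random_symmetric(5, rng) for _ in range(20)]
        cohort = make_cohort(mats, ["A"] * 10 + ["B"] * 10)
        with pytest.raises(ValueError, match="infeasible"):
            exhaustive_nbs_test(cohort, NBSConfig())


class TestNetworkMeanConnectivity:
    def test_single_edge(self, toy_cohort):
        res = NBS(toy_cohort, thresholds=[2.0]).fit(100, seed=0)
        comps = [c for cs in res.components.values() for c in cs]
        if not comps:
            pytest.skip("no component in fixture")
        comp = comps[0]
        net = network_mean_connectivity(toy_cohort, comp)
        iu = [e[0] for e in comp.edges]
        ju = [e[1] for e in comp.edges]
        brute = toy_cohort.weight_stack()[:, iu, ju].mean(axis=1)
        assert np.allclose(net, brute)

    def test_uniform_cohort_constant(self):
        m = np.ones((4, 4)) - np.eye(4)
        cohort = make_cohort([m.copy() for _ in range(4)], ["A", "A", "B", "B"])
        sm = edgewise_statistics(cohort, NBSConfig())
        comps = extract_components(stat_map_from_matrix(np.full((4, 4), 5.0) - np.eye(4) * 5), 3.0)
        net = network_mean_connectivity(cohort, comps[0])
        assert np.allclose(net, 1.0)
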