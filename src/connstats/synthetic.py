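"""Synthetic connectome cohorts with known ground truth.

The generator emulates a two-group structural connectome study: a shared
weighted template network (log-normal streamline-count-like weights on a
random topology), per-subject multiplicative log-normal noise, a *planted*
connected subnetwork whose weights are reduced in the patient group, and
behavioral scores drawn from published group summary statistics (ASRS
inattention / hyperactivity-impulsivity sums, continuous-performance-test
omission and commission error counts).

Because real participant connectomes cannot be shared, every downstream
stage (edge thresholding, network-based statistic, graph metrics) is
exercised against cohorts from this module, where the true effect — the
planted edge set and its effect size — is known exactly and recovery can be
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import BEHAVIOR_COLUMNS, ConnectomeMatrix, Cohort, canonical_edge

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "DEFAULT_BEHAVIOR_PARAMS",
    "plant_subnetwork",
    "generate_template",
    "generate_cohort",
    "recovery_score",
]

#: Group mean/SD of the normally distributed behavioral scores, and negative
#: binomial (mean, dispersion) for omission error counts.  Values reproduce
#: the published cohort characteristics (ADHD n=40 vs neurotypical n=36);
#: omission errors are calibrated to median 1 with interquartile range 0-3
#: (patients) and 0-1 (controls) to exercise the nonparametric branch.
DEFAULT_BEHAVIOR_PARAMS = {
    "inattention": {"ADHD": (23.36, 5.08), "NT": (12.78, 5.54)},
    "hyperactivity_impulsivity": {"ADHD": (19.58, 7.27), "NT": (10.19, 4.96)},
    "commission_errors": {"ADHD": (17.77, 7.01), "NT": (10.22, 5.48)},
    # negative binomial: (mean, dispersion r); var = mean + mean^2 / r
    "omission_errors": {"ADHD": (1.8, 1.0), "NT": (0.8, 1.0)},
}

#: Node-count presets: Destrieux + subcortical, and Schaefer-200 + 14
#: subcortical structures.
NODE_PRESETS = (164, 214)


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic cohort.

    Defaults reflect the emulated study: 164 nodes, 40 patients vs 36
    controls, dense connectivity, and log-normal weights whose masked-edge
    means span roughly 10-5000 streamlines so that the default group
    threshold of 10 is exercised.
    """

    n_nodes: int = 164
    n_per_group: tuple = (40, 36)
    group_names: tuple = ("ADHD", "NT")
    connection_density: float = 0.35
    base_weight_log_mean: float = 4.5
    base_weight_log_sd: float = 1.0
    subject_noise_log_sd: float = 0.2
    planted_n_nodes: int = 15
    planted_n_edges: int = 30
    effect_delta: float = 0.0
    behavior_params: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_BEHAVIOR_PARAMS.items()
        }
    )
    behavior_edge_coupling: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        n, k, m = self.n_nodes, self.planted_n_nodes, self.planted_n_edges
        if n < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0 < self.connection_density <= 1):
            raise ValueError("connection_density must be in (0, 1]")
        if not (0 <= self.effect_delta < 1):
            raise ValueError("effect_delta must be in [0, 1)")
        if k > n:
            raise ValueError("planted_n_nodes exceeds n_nodes")
        if m < k - 1 or m > k * (k - 1) // 2:
            raise ValueError(
                f"planted_n_edges={m} infeasible for {k} nodes "
                f"(needs {k - 1} <= m <= {k * (k - 1) // 2})"
            )
        if self.connection_density * n * (n - 1) / 2 < m:
            raise ValueError("expected edge count below planted_n_edges")
        if len(self.n_per_group) != 2 or min(self.n_per_group) < 2:
            raise ValueError("n_per_group must be two integers >= 2")
        if self.subject_noise_log_sd < 0 or self.base_weight_log_sd < 0:
            raise ValueError("log-sd parameters must be nonnegative")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """What was planted: the hypoconnected edge set and behavior coupling."""

    planted_edges: frozenset
    effect_delta: float
    behavior_coupling_edges: frozenset
    behavior_edge_coupling: float
    generator_seed: int


def _rngs(seed: int):
    """Independent child generators for plant/template/subjects/behavior."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(4)]


def plant_subnetwork(n_nodes: int, k_nodes: int, m_edges: int, seed: int) -> set:
    """A random connected subgraph: ``m_edges`` edges on ``k_nodes`` nodes.

    A uniform random spanning tree over a random node subset is grown first
    (guaranteeing connectivity), then extra edges are added uniformly among
    the remaining within-subset pairs.  Deterministic given ``seed``.
    """
    if k_nodes > n_nodes:
        raise ValueError("k_nodes exceeds n_nodes")
    if not (k_nodes - 1 <= m_edges <= k_nodes * (k_nodes - 1) // 2):
        raise ValueError(
            f"m_edges={m_edges} infeasible for k_nodes={k_nodes}"
        )
    rng = np.random.default_rng(seed)
    nodes = rng.choice(n_nodes, size=k_nodes, replace=False)
    # random spanning tree: attach each new node to a uniformly chosen
    # already-connected node
    order = rng.permutation(k_nodes)
    edges = set()
    for pos in range(1, k_nodes):
        a = nodes[order[pos]]
        b = nodes[order[rng.integers(0, pos)]]
        edges.add(canonical_edge(a, b))
    candidates = [
        canonical_edge(nodes[i], nodes[j])
        for i in range(k_nodes)
        for j in range(i + 1, k_nodes)
    ]
    pool = [e for e in candidates if e not in edges]
    extra = m_edges - len(edges)
    if extra > 0:
        chosen = rng.choice(len(pool), size=extra, replace=False)
        edges.update(pool[i] for i in chosen)
    return edges


def _planted_edges(config: SyntheticConfig) -> set:
    seed = np.random.SeedSequence(config.seed).spawn(4)[0]
    # derive a plain integer seed so plant_subnetwork stays callable on its own
    return plant_subnetwork(
        config.n_nodes,
        config.planted_n_nodes,
        config.planted_n_edges,
        seed=seed.generate_state(1)[0] % (2**31),
    )


def generate_template(config: SyntheticConfig, planted_edges=None) -> ConnectomeMatrix:
    """The shared group template network.

    Each node pair is connected independently with probability
    ``connection_density``; connected pairs get log-normal weights.  The
    planted edges are always present (weights drawn the same way), so the
    planted subnetwork is guaranteed to exist in every subject.
    """
    config.validate()
    if planted_edges is None:
        planted_edges = _planted_edges(config)
    _, rng, _, _ = _rngs(config.seed)
    n = config.n_nodes
    iu, ju = np.triu_indices(n, 1)
    present = rng.random(iu.size) < config.connection_density
    weights = np.where(
        present,
        rng.lognormal(config.base_weight_log_mean, config.base_weight_log_sd, iu.size),
        0.0,
    )
    w = np.zeros((n, n))
    w[iu, ju] = weights
    for (a, b) in planted_edges:
        if w[a, b] == 0:
            w[a, b] = rng.lognormal(
                config.base_weight_log_mean, config.base_weight_log_sd
            )
    w = w + w.T
    return ConnectomeMatrix(w)


def generate_cohort(config: SyntheticConfig):
    """Generate a full cohort plus its ground truth.

    Subject weights are ``template * exp(N(0, subject_noise_log_sd))``
    element-wise (symmetric noise); patient-group planted edges are further
    multiplied by ``1 - effect_delta``.  Behavioral scores are drawn from
    the per-group parameters; commission errors are additionally shifted by
    ``behavior_edge_coupling`` times the cohort-standardized mean weight
    over the planted edges, then floored at 0.  Error counts are rounded to
    integers.

    Returns
    -------
    (Cohort, SyntheticGroundTruth)
    """
    config.validate()
    planted = _planted_edges(config)
    template = generate_template(config, planted)
    _, _, rng_subj, rng_beh = _rngs(config.seed)

    n = config.n_nodes
    iu, ju = np.triu_indices(n, 1)
    tvals = template.weights[iu, ju]
    p_idx = np.array(
        [k for k, (a, b) in enumerate(zip(iu, ju)) if (a, b) in planted]
    )
    g1, g2 = config.group_names
    n1, n2 = config.n_per_group
    subject_ids, groups, connectomes = [], [], []
    reduction = 1.0 - config.effect_delta
    for s in range(n1 + n2):
        grp = g1 if s < n1 else g2
        noise = rng_subj.lognormal(0.0, config.subject_noise_log_sd, iu.size)
        vals = tvals * noise
        if grp == g1:
            vals[p_idx] = vals[p_idx] * reduction
        w = np.zeros((n, n))
        w[iu, ju] = vals
        w = w + w.T
        subject_ids.append(f"sub-{s + 1:03d}")
        groups.append(grp)
        connectomes.append(ConnectomeMatrix(w))

    behavior = _generate_behavior(
        config, rng_beh, subject_ids, groups, connectomes, planted
    )
    cohort = Cohort(
        subject_ids=subject_ids,
        groups=groups,
        connectomes=connectomes,
        behavior=behavior,
    )
    truth = SyntheticGroundTruth(
        planted_edges=frozenset(planted),
        effect_delta=config.effect_delta,
        behavior_coupling_edges=frozenset(planted),
        behavior_edge_coupling=config.behavior_edge_coupling,
        generator_seed=config.seed,
    )
    return cohort, truth


def _generate_behavior(config, rng, subject_ids, groups, connectomes, planted):
    params = config.behavior_params
    n_subj = len(subject_ids)
    data = {}
    for var in ("inattention", "hyperactivity_impulsivity", "commission_errors"):
        vals = np.empty(n_subj)
        for i, g in enumerate(groups):
            m, s = params[var][g]
            vals[i] = rng.normal(m, s)
        data[var] = vals
    # omission errors: negative binomial, exercised by the nonparametric path
    om = np.empty(n_subj)
    for i, g in enumerate(groups):
        mean, r = params["omission_errors"][g]
        p = r / (r + mean)
        om[i] = rng.negative_binomial(r, p)
    data["omission_errors"] = om

    if config.behavior_edge_coupling != 0.0 and planted:
        edges = sorted(planted)
        iu = np.array([e[0] for e in edges])
        ju = np.array([e[1] for e in edges])
        net_mean = np.array(
            [c.weights[iu, ju].mean() for c in connectomes]
        )
        z = (net_mean - net_mean.mean()) / net_mean.std(ddof=1)
        data["commission_errors"] = (
            data["commission_errors"] + config.behavior_edge_coupling * z
        )

    data["commission_errors"] = np.clip(np.rint(data["commission_errors"]), 0, None)
    data["omission_errors"] = np.clip(np.rint(data["omission_errors"]), 0, None)
    return pd.DataFrame(
        {k: data[k] for k in BEHAVIOR_COLUMNS}, index=pd.Index(subject_ids, name="subject_id")
    )


def recovery_score(found_edges, truth_or_edges) -> float:
    """Jaccard index between a recovered edge set and the planted edges.

    Both sets empty is defined as 0.
    """
    if isinstance(truth_or_edges, SyntheticGroundTruth):
        planted = set(truth_or_edges.planted_edges)
    else:
        planted = {canonical_edge(*e) for e in truth_or_edges}
    found = {canonical_edge(*e) for e in found_edges}
    union = found | planted
    if not union:
        return 0.0
    return len(found & planted) / len(union)
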