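"""The network-based statistic (NBS) for weighted connectome cohorts.

NBS controls family-wise error at the level of connected subnetworks rather
than single edges.  The procedure: (1) compute a test statistic on every
analyzable edge (a one-tailed two-sample t for group designs; Pearson r
mapped to the t scale for behavioral-correlation designs); (2) form the
connected components of the graph of edges whose statistic exceeds a
threshold; (3) size each component by *extent* (edge count) and *intensity*
(sum of edge statistics); (4) permute group labels (or the behavioral
vector) many times, recording the largest component size per permutation,
and report for each observed component the proportion of permutations whose
maximum size reached it.

The entry point is the :class:`NBS` model class: build it from a
:class:`~connstats.connectome.Cohort`, call :meth:`NBS.fit`, and read the
returned :class:`NBSResult` (components, FWE p values, null distribution,
``summary()``).  Functional wrappers :func:`nbs_test` and
:func:`exhaustive_nbs_test` cover scripted use.

Permutation p values are the proportion of permutations with a max
component at least as large as the observed component; the observed
labelling is *not* counted among the permutations, so p = 0 is possible and
is rendered as "< 1/n_permutations" in summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .connectome import Cohort, canonical_edge

__all__ = [
    "NBS",
    "NBSConfig",
    "EdgeStatMap",
    "NBSComponent",
    "NBSResult",
    "edgewise_statistics",
    "extract_components",
    "component_size",
    "nbs_test",
    "exhaustive_nbs_test",
    "network_mean_connectivity",
]

_PERM_CHUNK = 256  # permutations per vectorized block

#: cap applied to |t| from a degenerate (|r| -> 1) correlation edge
_R_CLIP = 1.0 - 1e-12


@dataclass
class NBSConfig:
    """Parameters of one NBS analysis.

    ``size_measure`` designates the primary component-size measure; both
    extent and intensity are always computed.  Intensity is the default
    primary because its permutation distribution is continuous, giving
    essentially exact max-statistic p values, while extent is integer-valued
    and lumpy when few edges cross the threshold.
    ``direction`` is ``group1_less``/``group1_greater`` for group designs
    (group 1 = first group label in the cohort) and ``negative``/``positive``
    for correlation designs.
    """

    thresholds: tuple = (3.0, 3.5, 4.0)
    size_measure: str = "intensity"
    n_permutations: int = 10000
    design: str = "group_difference"
    direction: str = "group1_less"
    alpha: float = 0.05
    seed: int = 0
    intensity_excess: bool = False  # sum (stat - threshold) instead of sum stat

    def validate(self):
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.size_measure not in ("extent", "intensity"):
            raise ValueError("size_measure must be 'extent' or 'intensity'")
        if self.design not in ("group_difference", "correlation"):
            raise ValueError("design must be 'group_difference' or 'correlation'")
        valid = (
            ("group1_less", "group1_greater")
            if self.design == "group_difference"
            else ("negative", "positive")
        )
        if self.direction not in valid:
            raise ValueError(
                f"direction {self.direction!r} invalid for design {self.design!r}"
            )
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class EdgeStatMap:
    """Per-edge statistics over the cohort's masked edges."""

    stats: np.ndarray  # (n_edges,) signed statistic on the t scale
    iu: np.ndarray
    ju: np.ndarray
    n_nodes: int
    df: float
    design: str
    direction: str
    flagged: np.ndarray = None  # degenerate edges (zero variance / |r|=1)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.flagged is None:
            self.flagged = np.zeros(len(self.stats), dtype=bool)

    def as_matrix(self) -> np.ndarray:
        """Symmetric dense statistic matrix, NaN outside the edge mask."""
        m = np.full((self.n_nodes, self.n_nodes), np.nan)
        m[self.iu, self.ju] = self.stats
        m[self.ju, self.iu] = self.stats
        return m


@dataclass
class NBSComponent:
    """A suprathreshold connected component with its FWE p values."""

    nodes: frozenset
    edges: tuple  # canonical (i, j) pairs, sorted
    edge_stats: tuple
    extent: int
    intensity: float
    threshold: float
    p_fwe: float = math.nan  # primary size measure
    p_fwe_extent: float = math.nan
    p_fwe_intensity: float = math.nan


def _fraction_ge(null_values: np.ndarray, observed: float, measure: str) -> float:
    """Fraction of null values >= observed.

    Intensities are compared with a tiny relative tolerance: the observed
    component's sum and the permutation accumulator add the same floats in
    different orders, and strict comparison would otherwise miss exact
    re-occurrences of the observed labelling.
    """
    if measure == "intensity":
        tol = 1e-9 * max(1.0, abs(observed))
        return float(np.mean(null_values >= observed - tol))
    return float(np.mean(null_values >= observed))


def component_size(component: NBSComponent, measure: str) -> float:
    """Component size under a measure: 'extent' (edges) or 'intensity' (sum t)."""
    if measure == "extent":
        return component.extent
    if measure == "intensity":
        return component.intensity
    raise ValueError(f"unknown size measure {measure!r}")


# ---------------------------------------------------------------------------
# edge-wise statistics (vectorized over edges and permutations)
# ---------------------------------------------------------------------------

def _group_t_block(X, X2, member1, n1, n2, sign):
    """Pooled t for one block of group-1 membership indicators.

    member1 : (B, n_subjects) float 0/1 matrix with row sums n1.
    Returns (B, n_edges) statistics; zero-variance edges get 0.
    """
    s1 = member1 @ X
    q1 = member1 @ X2
    s2 = X.sum(axis=0) - s1
    q2 = X2.sum(axis=0) - q1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = np.maximum(q1 - n1 * m1**2, 0.0)
    ss2 = np.maximum(q2 - n2 * m2**2, 0.0)
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = sign * (m2 - m1) / se
    t[se == 0] = 0.0
    return t


def _corr_t_block(Xc, sx, Y, sign):
    """Correlation t statistics for a block of (possibly permuted) behaviors.

    Xc : (n_subjects, n_edges) column-centered weights; sx their SDs (ddof=1).
    Y : (B, n_subjects) centered behavioral vectors.
    """
    n = Xc.shape[0]
    sy = Y.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Y @ Xc) / ((n - 1) * np.outer(sy, sx))
    r[:, sx == 0] = 0.0
    clipped = np.abs(r) > _R_CLIP
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    t = sign * r * math.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    return t, clipped


def edgewise_statistics(cohort: Cohort, config: NBSConfig, behavior=None) -> EdgeStatMap:
    """Statistic map over the masked edges for one design.

    Group design: pooled one-tailed two-sample t per edge, signed so that
    the configured direction gives positive statistics.  Correlation design:
    Pearson r of edge weight with the named behavioral variable, mapped to
    the t scale (df = n - 2) so thresholds are comparable across designs.
    Edges with zero variance across subjects get statistic 0 and a flag (a
    constant edge can never exceed a positive threshold); degenerate |r| = 1
    edges are clipped to a maximal finite t and flagged.
    """
    config.validate()
    X, iu, ju = cohort.edge_data_matrix()
    if config.design == "group_difference":
        g1, g2 = cohort.group_names
        i1 = cohort.group_indices(g1)
        n1, n2 = len(i1), cohort.n_subjects - len(i1)
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs >= 2 subjects")
        sign = 1.0 if config.direction == "group1_less" else -1.0
        member1 = np.zeros((1, cohort.n_subjects))
        member1[0, i1] = 1.0
        X2 = X**2
        stats = _group_t_block(X, X2, member1, n1, n2, sign)[0]
        # exact zero-variance edges: flag and zero out (cancellation in the
        # vectorized sums otherwise leaves O(1e-8) noise there)
        flagged = np.ptp(X, axis=0) == 0
        stats[flagged] = 0.0
        return EdgeStatMap(
            stats, iu, ju, cohort.n_nodes, df=n1 + n2 - 2,
            design=config.design, direction=config.direction, flagged=flagged,
            meta={"group_sizes": (n1, n2), "groups": (g1, g2)},
        )
    # correlation design
    if behavior is None:
        raise ValueError("correlation design requires a behavioral variable")
    y = np.asarray(cohort.behavior[behavior], dtype=float)
    keep = np.isfinite(y)
    if keep.sum() < 4:
        raise ValueError("need >= 4 subjects with non-missing behavior")
    Xk = X[keep]
    yk = y[keep]
    if yk.std(ddof=1) == 0:
        raise ValueError("constant behavioral vector")
    sign = 1.0 if config.direction == "positive" else -1.0
    Xc = Xk - Xk.mean(axis=0)
    sx = Xk.std(axis=0, ddof=1)
    stats, clipped = _corr_t_block(Xc, sx, (yk - yk.mean())[None, :], sign)
    flagged = (sx == 0) | clipped[0]
    return EdgeStatMap(
        stats[0], iu, ju, cohort.n_nodes, df=keep.sum() - 2,
        design=config.design, direction=config.direction, flagged=flagged,
        meta={"behavior": behavior, "n": int(keep.sum())},
    )


# ---------------------------------------------------------------------------
# connected components of suprathreshold edges
# ---------------------------------------------------------------------------

def _union_find_components(iu, ju):
    """Connected components over an edge list; returns list of edge-index lists."""
    parent = {}

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    comp_edges = {}
    for k, (a, b) in enumerate(zip(iu, ju)):
        for x in (a, b):
            if x not in parent:
                parent[x] = x
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
        comp_edges.setdefault(find(a), []).append(k)
    # merge edge lists whose roots collapsed later
    merged = {}
    for root, ks in comp_edges.items():
        merged.setdefault(find(root), []).extend(ks)
    return list(merged.values())


def extract_components(stat_map: EdgeStatMap, threshold: float,
                       primary: str = "intensity",
                       intensity_excess: bool = False):
    """Connected components of edges with statistic > threshold.

    Components are sorted by the primary size measure, descending, ties
    broken by smallest node index.  p values are not filled in here.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sel = np.flatnonzero(stat_map.stats > threshold)
    if sel.size == 0:
        return []
    iu = stat_map.iu[sel]
    ju = stat_map.ju[sel]
    vals = stat_map.stats[sel]
    comps = []
    for edge_idx in _union_find_components(iu, ju):
        edge_idx = sorted(edge_idx)
        edges = tuple(
            canonical_edge(iu[k], ju[k]) for k in edge_idx
        )
        stats = tuple(float(vals[k]) for k in edge_idx)
        contrib = (
            sum(s - threshold for s in stats) if intensity_excess else sum(stats)
        )
        nodes = frozenset(i for e in edges for i in e)
        comps.append(
            NBSComponent(
                nodes=nodes,
                edges=tuple(sorted(edges)),
                edge_stats=stats,
                extent=len(edges),
                intensity=float(contrib),
                threshold=threshold,
            )
        )
    comps.sort(key=lambda c: (-component_size(c, primary), min(c.nodes)))
    return comps


def _max_sizes(stats_row, iu, ju, threshold, intensity_excess):
    """(max extent, max intensity) over components of one statistic vector."""
    sel = np.flatnonzero(stats_row > threshold)
    if sel.size == 0:
        return 0, 0.0
    parent = {}

    def find(a):
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:
            parent[a], a = root, parent[a]
        return root

    ext = {}
    inten = {}
    for k in sel:
        a, b = int(iu[k]), int(ju[k])
        for x in (a, b):
            if x not in parent:
                parent[x] = x
                ext[x] = 0
                inten[x] = 0.0
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
            ext[ra] += ext.pop(rb)
            inten[ra] += inten.pop(rb)
        r = find(a)
        ext[r] += 1
        v = float(stats_row[k])
        inten[r] += (v - threshold) if intensity_excess else v
    roots = [x for x in parent if parent[x] == x]
    return max(ext[r] for r in roots), max(inten[r] for r in roots)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class NBSResult:
    """Fitted NBS analysis: components, null distribution, diagnostics.

    ``components[threshold]`` lists :class:`NBSComponent` sorted by the
    primary size measure; ``null_max_sizes[threshold]`` holds the per-
    permutation largest component size for both measures, so every reported
    p value is reproducible from the stored null distribution.
    """

    config: NBSConfig
    stat_map: EdgeStatMap
    components: dict
    null_max_sizes: dict
    n_permutations: int
    seed: int
    warnings: list = field(default_factory=list)
    exhaustive: bool = False

    def significant_components(self, alpha=None, threshold=None):
        alpha = self.config.alpha if alpha is None else alpha
        out = []
        for thr, comps in self.components.items():
            if threshold is not None and thr != threshold:
                continue
            out.extend(c for c in comps if c.p_fwe < alpha)
        return out

    def format_p(self, p: float) -> str:
        if p == 0:
            return f"< {1.0 / self.n_permutations:g}"
        return f"{p:.4g}"

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Network-based statistic",
            "=" * 60,
            f"design: {cfg.design}   direction: {cfg.direction}",
            f"permutations: {self.n_permutations}"
            + ("  (exhaustive enumeration)" if self.exhaustive else "")
            + f"   seed: {self.seed}",
            f"primary size measure: {cfg.size_measure}",
            f"edges tested: {len(self.stat_map.stats)}   df: {self.stat_map.df:g}",
            "-" * 60,
            f"{'thr':>5} {'comp':>4} {'extent':>6} {'intensity':>10} "
            f"{'p_ext':>8} {'p_int':>8}",
        ]
        for thr in cfg.thresholds:
            comps = self.components.get(thr, [])
            if not comps:
                lines.append(f"{thr:>5.2f}    - no suprathreshold component")
                continue
            for k, c in enumerate(comps, 1):
                lines.append(
                    f"{thr:>5.2f} {k:>4} {c.extent:>6} {c.intensity:>10.2f} "
                    f"{self.format_p(c.p_fwe_extent):>8} "
                    f"{self.format_p(c.p_fwe_intensity):>8}"
                )
        if self.warnings:
            lines.append("-" * 60)
            lines.extend(f"warning: {w}" for w in self.warnings)
        return "\n".join(lines)

    def plot_null_distribution(self, threshold=None, ax=None):
        """Histogram of the permutation null of the max component size."""
        from .plotting import plot_null_distribution

        return plot_null_distribution(self, threshold=threshold, ax=ax)


# ---------------------------------------------------------------------------
# the model class
# ---------------------------------------------------------------------------

class NBS:
    """Network-based statistic model over a cohort.

    Parameters
    ----------
    cohort : Cohort
        Must carry an edge mask (see
        :func:`connstats.connectome.group_threshold`).
    design : {'group_difference', 'correlation'}
    direction : str
        ``group1_less`` / ``group1_greater`` (group 1 is the first group
        label in the cohort, conventionally the patient group) or
        ``negative`` / ``positive`` for correlation designs.
    behavior : str, optional
        Behavioral column for correlation designs.
    thresholds : sequence of float
        Edge-statistic thresholds on the t scale.
    size_measure : {'intensity', 'extent'}
        Primary component-size measure (both are always computed).

    Examples
    --------
    >>> model = NBS(cohort, direction="group1_less", thresholds=[3.0])
    >>> result = model.fit(n_permutations=1000, seed=7)
    >>> print(result.summary())
    """

    def __init__(self, cohort: Cohort, design="group_difference",
                 direction=None, behavior=None, thresholds=(3.0, 3.5, 4.0),
                 size_measure="intensity", alpha=0.05, intensity_excess=False):
        if direction is None:
            direction = "group1_less" if design == "group_difference" else "negative"
        self.cohort = cohort
        self.behavior = behavior
        self.config = NBSConfig(
            thresholds=tuple(thresholds),
            size_measure=size_measure,
            design=design,
            direction=direction,
            alpha=alpha,
            intensity_excess=intensity_excess,
        )
        self.config.validate()
        if design == "correlation" and behavior is None:
            raise ValueError("correlation design requires behavior=")

    # -- permutation engines ----------------------------------------------
    def _perm_blocks(self, n_permutations, seed, n_subjects):
        """Yield blocks of permuted subject orders, derived from (seed, i)."""
        for start in range(0, n_permutations, _PERM_CHUNK):
            stop = min(start + _PERM_CHUNK, n_permutations)
            block = np.empty((stop - start, n_subjects), dtype=np.intp)
            for i in range(start, stop):
                block[i - start] = np.random.default_rng([seed, i]).permutation(
                    n_subjects
                )
            yield block

    def fit(self, n_permutations=10000, seed=0) -> NBSResult:
        """Run the permutation test; deterministic given ``seed``."""
        cfg = self.config
        cfg.n_permutations = int(n_permutations)
        cfg.seed = int(seed)
        cfg.validate()
        stat_map = edgewise_statistics(self.cohort, cfg, self.behavior)
        iu, ju = stat_map.iu, stat_map.ju
        thresholds = cfg.thresholds
        null_max = {
            thr: {
                "extent": np.zeros(n_permutations),
                "intensity": np.zeros(n_permutations),
            }
            for thr in thresholds
        }
        X, _, _ = self.cohort.edge_data_matrix()
        if cfg.design == "group_difference":
            g1 = self.cohort.group_names[0]
            i1 = self.cohort.group_indices(g1)
            n1 = len(i1)
            n2 = self.cohort.n_subjects - n1
            sign = 1.0 if cfg.direction == "group1_less" else -1.0
            X2 = X**2
            pos = 0
            for block in self._perm_blocks(n_permutations, seed, self.cohort.n_subjects):
                member1 = np.zeros((block.shape[0], self.cohort.n_subjects))
                rows = np.repeat(np.arange(block.shape[0]), n1)
                member1[rows, block[:, :n1].ravel()] = 1.0
                tblock = _group_t_block(X, X2, member1, n1, n2, sign)
                self._record_block(
                    tblock, iu, ju, thresholds, null_max, pos, cfg.intensity_excess
                )
                pos += block.shape[0]
        else:
            y = np.asarray(self.cohort.behavior[self.behavior], dtype=float)
            keep = np.isfinite(y)
            Xk = X[keep]
            yk = y[keep]
            Xc = Xk - Xk.mean(axis=0)
            sx = Xk.std(axis=0, ddof=1)
            yc = yk - yk.mean()
            sign = 1.0 if cfg.direction == "positive" else -1.0
            nk = len(yk)
            pos = 0
            for block in self._perm_blocks(n_permutations, seed, nk):
                Y = yc[block]
                tblock, _ = _corr_t_block(Xc, sx, Y, sign)
                self._record_block(
                    tblock, iu, ju, thresholds, null_max, pos, cfg.intensity_excess
                )
                pos += block.shape[0]

        components = {}
        warnings = []
        if n_permutations < 1.0 / cfg.alpha:
            warnings.append(
                f"{n_permutations} permutations cannot resolve alpha={cfg.alpha}"
            )
        for thr in thresholds:
            comps = extract_components(
                stat_map, thr, primary=cfg.size_measure,
                intensity_excess=cfg.intensity_excess,
            )
            for c in comps:
                c.p_fwe_extent = _fraction_ge(
                    null_max[thr]["extent"], c.extent, "extent"
                )
                c.p_fwe_intensity = _fraction_ge(
                    null_max[thr]["intensity"], c.intensity, "intensity"
                )
                c.p_fwe = (
                    c.p_fwe_extent if cfg.size_measure == "extent" else c.p_fwe_intensity
                )
            components[thr] = comps
        return NBSResult(
            config=cfg, stat_map=stat_map, components=components,
            null_max_sizes=null_max, n_permutations=n_permutations,
            seed=seed, warnings=warnings,
        )

    @staticmethod
    def _record_block(tblock, iu, ju, thresholds, null_max, pos, intensity_excess):
        for b in range(tblock.shape[0]):
            row = tblock[b]
            for thr in thresholds:
                ext, inten = _max_sizes(row, iu, ju, thr, intensity_excess)
                null_max[thr]["extent"][pos + b] = ext
                null_max[thr]["intensity"][pos + b] = inten


# ---------------------------------------------------------------------------
# functional wrappers and the exhaustive oracle
# ---------------------------------------------------------------------------

def nbs_test(cohort: Cohort, config: NBSConfig, behavior=None) -> NBSResult:
    """Run NBS per a config object (see :class:`NBS` for the model API)."""
    config.validate()
    model = NBS(
        cohort,
        design=config.design,
        direction=config.direction,
        behavior=behavior,
        thresholds=config.thresholds,
        size_measure=config.size_measure,
        alpha=config.alpha,
        intensity_excess=config.intensity_excess,
    )
    return model.fit(n_permutations=config.n_permutations, seed=config.seed)


def exhaustive_nbs_test(cohort: Cohort, config: NBSConfig) -> NBSResult:
    """NBS with every group-label assignment enumerated exactly once.

    Small-cohort oracle for the Monte-Carlo permutation test: the null
    distribution has exactly C(n, n1) entries (the observed labelling
    included once, like any other assignment).  Refuses combinatorially
    infeasible inputs (> 10,000 assignments).
    """
    config.validate()
    if config.design != "group_difference":
        raise ValueError("exhaustive enumeration applies to group designs")
    g1 = cohort.group_names[0]
    i1 = cohort.group_indices(g1)
    n1 = len(i1)
    n = cohort.n_subjects
    n_assign = math.comb(n, n1)
    if n_assign > 10000:
        raise ValueError(f"{n_assign} assignments: combinatorially infeasible")
    X, iu, ju = cohort.edge_data_matrix()
    X2 = X**2
    n2 = n - n1
    sign = 1.0 if config.direction == "group1_less" else -1.0
    member1 = np.zeros((n_assign, n))
    for k, combo in enumerate(itertools.combinations(range(n), n1)):
        member1[k, list(combo)] = 1.0
    tall = _group_t_block(X, X2, member1, n1, n2, sign)
    stat_map = edgewise_statistics(cohort, config)
    null_max = {
        thr: {"extent": np.zeros(n_assign), "intensity": np.zeros(n_assign)}
        for thr in config.thresholds
    }
    for thr in config.thresholds:
        for k in range(n_assign):
            ext, inten = _max_sizes(tall[k], iu, ju, thr, config.intensity_excess)
            null_max[thr]["extent"][k] = ext
            null_max[thr]["intensity"][k] = inten
    components = {}
    for thr in config.thresholds:
        comps = extract_components(
            stat_map, thr, primary=config.size_measure,
            intensity_excess=config.intensity_excess,
        )
        for c in comps:
            c.p_fwe_extent = _fraction_ge(null_max[thr]["extent"], c.extent, "extent")
            c.p_fwe_intensity = _fraction_ge(
                null_max[thr]["intensity"], c.intensity, "intensity"
            )
            c.p_fwe = (
                c.p_fwe_extent
                if config.size_measure == "extent"
                else c.p_fwe_intensity
            )
        components[thr] = comps
    return NBSResult(
        config=config, stat_map=stat_map, components=components,
        null_max_sizes=null_max, n_permutations=n_assign,
        seed=config.seed, exhaustive=True,
    )


def network_mean_connectivity(cohort: Cohort, component: NBSComponent) -> np.ndarray:
    """Per-subject mean edge weight over a component's edges.

    The vector feeds behavioral correlations and group effect sizes for a
    significant subnetwork.
    """
    if not component.edges:
        raise ValueError("empty component")
    for e in component.edges:
        if not cohort.edge_mask[e]:
            raise ValueError(f"component edge {e} outside the cohort edge mask")
    iu = np.array([e[0] for e in component.edges])
    ju = np.array([e[1] for e in component.edges])
    return cohort.weight_stack()[:, iu, ju].mean(axis=1)
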