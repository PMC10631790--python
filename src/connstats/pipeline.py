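"""End-to-end study workflow over a connectome cohort.

Stages: cohort characteristics table -> group-difference NBS at every
threshold and both directions -> behavioral-correlation NBS -> graph-metric
group comparison with null-model normalization -> outlier-sensitivity NBS
re-run.  :func:`full_report` chains them, writes a machine-readable
``report.json`` plus human-readable TSV tables, and logs seeds so the whole
run is reproducible.  Stage failures are recorded with provenance and a
partial report is still emitted.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .connectome import (
    Cohort,
    detect_edge_outliers,
    group_threshold,
    load_cohort,
    total_streamline_report,
)
from .nbs import NBS, NBSResult, network_mean_connectivity
from .nulls import normalize_profile, null_ensemble
from .metrics import compute_profile
from .stats import (
    TestResult,
    bonferroni_adjust,
    cohens_d,
    correlate,
    mann_whitney_u,
    one_way_anova,
    t_test,
)
from .synthetic import recovery_score

__all__ = [
    "AnalysisConfig",
    "StudyReport",
    "run_cohort_characteristics",
    "run_group_nbs",
    "run_behavior_nbs",
    "run_graph_comparison",
    "run_sensitivity_rerun",
    "full_report",
    "validate_report",
]

logger = logging.getLogger("connstats")

#: default per-variable test designation (normality gating is explicit
#: config here, not data-driven)
DEFAULT_DESIGNATIONS = {
    "inattention": "parametric",
    "hyperactivity_impulsivity": "welch",
    "commission_errors": "parametric",
    "omission_errors": "nonparametric",
}


@dataclass
class AnalysisConfig:
    """Everything a full study run needs, JSON round-trippable."""

    manifest_path: str = None
    output_dir: str = "connstats_output"
    # edge selection
    min_mean_weight: float = 10.0
    # NBS
    thresholds: tuple = (3.0, 3.5, 4.0)
    n_permutations: int = 10000
    size_measure: str = "intensity"
    intensity_excess: bool = False
    alpha: float = 0.05
    # graph metrics
    gamma: float = 1.0
    n_null: int = 100
    louvain_repeats: int = 100
    k_values: tuple = None
    # behavior
    behavioral_variables: dict = field(
        default_factory=lambda: dict(DEFAULT_DESIGNATIONS)
    )
    # sensitivity re-run
    outlier_sd_factor: float = 2.0
    outlier_min_edges: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        if cfg.thresholds is not None:
            cfg.thresholds = tuple(cfg.thresholds)
        if cfg.k_values is not None:
            cfg.k_values = tuple(cfg.k_values)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        if self.k_values is not None:
            d["k_values"] = list(self.k_values)
        return d


@dataclass
class StudyReport:
    """Assembled study output; ``to_dict`` is the report.json payload."""

    config: AnalysisConfig
    characteristics: pd.DataFrame = None
    group_nbs: dict = None
    behavior_nbs: dict = None
    graph: dict = None
    sensitivity: dict = None
    streamline_screening: pd.DataFrame = None
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "package_version": __version__,
                "seed": self.config.seed,
                "config": self.config.to_dict(),
            },
            "characteristics": _df_records(self.characteristics),
            "group_nbs": self.group_nbs,
            "behavior_nbs": self.behavior_nbs,
            "graph": self.graph,
            "sensitivity": self.sensitivity,
            "streamline_screening": _df_records(self.streamline_screening),
            "errors": self.errors,
        }


def _df_records(df):
    if df is None:
        return None
    return json.loads(df.to_json(orient="records"))


def _tr_dict(tr: TestResult, correction_scope: str = "none", p_adj=None) -> dict:
    df = tr.df
    if isinstance(df, tuple):
        df = list(df)
    elif df is not None and not (isinstance(df, float) and np.isnan(df)):
        df = float(df)
    else:
        df = None
    out = {
        "test": tr.name,
        "statistic": float(tr.statistic),
        "df": df,
        "p": float(tr.p_value),
        "tail": tr.tail,
        "correction_scope": correction_scope,
    }
    if tr.estimate is not None:
        out["estimate"] = float(tr.estimate)
    if p_adj is not None:
        out["p_adjusted"] = float(p_adj)
    return out


# ---------------------------------------------------------------------------
# stage 1: cohort characteristics
# ---------------------------------------------------------------------------

def run_cohort_characteristics(cohort: Cohort, config: AnalysisConfig) -> pd.DataFrame:
    """Per-variable group summaries and the designated test.

    Parametric variables get M(SD) and a pooled (or Welch) t; nonparametric
    ones get Mdn(IQR) and a Mann-Whitney U.  Missing values are removed per
    variable, with the reduced n reflected in the df.
    """
    g1, g2 = cohort.group_names
    i1, i2 = cohort.group_indices(g1), cohort.group_indices(g2)
    rows = []
    for var, designation in config.behavioral_variables.items():
        if var not in cohort.behavior.columns:
            raise ValueError(f"behavioral variable {var!r} missing from cohort")
        if designation not in ("parametric", "welch", "nonparametric"):
            raise ValueError(
                f"variable {var!r} has unknown designation {designation!r}"
            )
        v = np.asarray(cohort.behavior[var], dtype=float)
        x = v[i1][np.isfinite(v[i1])]
        y = v[i2][np.isfinite(v[i2])]
        if designation == "nonparametric":
            tr = mann_whitney_u(x, y)
            s1 = f"{np.median(x):.2f} ({np.percentile(x, 25):.0f}-{np.percentile(x, 75):.0f})"
            s2 = f"{np.median(y):.2f} ({np.percentile(y, 25):.0f}-{np.percentile(y, 75):.0f})"
        else:
            variant = "welch" if designation == "welch" else "pooled"
            tr = t_test(x, y, variant=variant)
            s1 = f"{x.mean():.2f} ({x.std(ddof=1):.2f})"
            s2 = f"{y.mean():.2f} ({y.std(ddof=1):.2f})"
        rows.append(
            {
                "variable": var,
                f"{g1} (n={len(x)})": s1,
                f"{g2} (n={len(y)})": s2,
                "test": tr.name,
                "statistic": round(float(tr.statistic), 4),
                "df": None if isinstance(tr.df, float) and np.isnan(tr.df) else tr.df,
                "p": float(tr.p_value),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage 2 & 3: NBS sections
# ---------------------------------------------------------------------------

def _component_dict(cohort, comp, result: NBSResult) -> dict:
    labels = cohort.node_labels
    return {
        "threshold": comp.threshold,
        "extent": comp.extent,
        "intensity": comp.intensity,
        "p_fwe": comp.p_fwe,
        "p_fwe_extent": comp.p_fwe_extent,
        "p_fwe_intensity": comp.p_fwe_intensity,
        "p_display": result.format_p(comp.p_fwe),
        "n_nodes": len(comp.nodes),
        "edges": [
            {
                "node_i": int(i),
                "node_j": int(j),
                "label_i": labels[i],
                "label_j": labels[j],
                "statistic": float(s),
            }
            for (i, j), s in zip(comp.edges, comp.edge_stats)
        ],
    }


def _nbs_section(cohort, result: NBSResult, alpha) -> dict:
    section = {
        "direction": result.config.direction,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "thresholds": {},
        "warnings": result.warnings,
    }
    for thr, comps in result.components.items():
        section["thresholds"][f"{thr:g}"] = {
            "n_components": len(comps),
            "components": [_component_dict(cohort, c, result) for c in comps],
            "significant": [
                _component_dict(cohort, c, result) for c in comps if c.p_fwe < alpha
            ],
            "smallest_p": min((c.p_fwe for c in comps), default=None),
        }
    return section


def run_group_nbs(cohort: Cohort, config: AnalysisConfig) -> dict:
    """Group-difference NBS: every threshold x both directions x both sizes."""
    out = {}
    for direction in ("group1_less", "group1_greater"):
        model = NBS(
            cohort,
            design="group_difference",
            direction=direction,
            thresholds=config.thresholds,
            size_measure=config.size_measure,
            alpha=config.alpha,
            intensity_excess=config.intensity_excess,
        )
        result = model.fit(n_permutations=config.n_permutations, seed=config.seed)
        out[direction] = _nbs_section(cohort, result, config.alpha)
        out[direction]["_result"] = result  # stripped before serialization
    return out


def run_behavior_nbs(cohort: Cohort, config: AnalysisConfig, variable: str) -> dict:
    """Correlation-design NBS for one behavioral variable, both signs.

    For each significant component the per-subject network mean
    connectivity is exported together with a group-split Cohen's d (the
    effect size of the group difference in that network's mean weight).
    """
    out = {"variable": variable}
    g1, g2 = cohort.group_names
    i1, i2 = cohort.group_indices(g1), cohort.group_indices(g2)
    for direction in ("negative", "positive"):
        model = NBS(
            cohort,
            design="correlation",
            direction=direction,
            behavior=variable,
            thresholds=config.thresholds,
            size_measure=config.size_measure,
            alpha=config.alpha,
            intensity_excess=config.intensity_excess,
        )
        result = model.fit(n_permutations=config.n_permutations, seed=config.seed)
        section = _nbs_section(cohort, result, config.alpha)
        for thr, comps in result.components.items():
            sig_dicts = section["thresholds"][f"{thr:g}"]["significant"]
            sig_comps = [c for c in comps if c.p_fwe < config.alpha]
            for comp_dict, comp in zip(sig_dicts, sig_comps):
                net = network_mean_connectivity(cohort, comp)
                comp_dict["network_mean_connectivity"] = net.tolist()
                comp_dict["cohens_d_group_split"] = cohens_d(net[i1], net[i2])
        out[direction] = section
        out[direction]["_result"] = result
    return out


# ---------------------------------------------------------------------------
# stage 4: graph metric comparison
# ---------------------------------------------------------------------------

GLOBAL_METRICS = (
    "mean_strength",
    "mean_betweenness",
    "norm_clustering",
    "norm_path_length",
    "norm_efficiency",
    "norm_modularity",
    "small_worldness",
)

LOCAL_METRICS = ("strength", "betweenness", "local_efficiency", "clustering")


def _subject_profiles(cohort: Cohort, config: AnalysisConfig):
    """Per-subject normalized profiles (the expensive part of stage 4)."""
    ss = np.random.SeedSequence(config.seed).spawn(cohort.n_subjects)
    profiles = []
    for s, c in enumerate(cohort.connectomes):
        seed_s = int(ss[s].generate_state(1)[0] % (2**31))
        masked = c.weights * cohort.edge_mask
        prof = compute_profile(
            masked,
            gamma=config.gamma,
            louvain_repeats=config.louvain_repeats,
            seed=seed_s,
            k_values=config.k_values,
        )
        ens = null_ensemble(
            type(c)(masked, list(c.labels)),
            n=config.n_null,
            seed=seed_s,
            gamma=config.gamma,
            louvain_repeats=max(1, config.louvain_repeats // 10),
            k_values=config.k_values,
        )
        normalize_profile(prof, ens)
        profiles.append(prof)
    return profiles


def _global_value(prof, metric):
    if metric == "mean_strength":
        return prof.mean_strength
    if metric == "mean_betweenness":
        return float(prof.betweenness.mean())
    if metric == "norm_clustering":
        return prof.normalized["mean_clustering"]
    if metric == "norm_path_length":
        return prof.normalized["characteristic_path_length"]
    if metric == "norm_efficiency":
        return prof.normalized["global_efficiency"]
    if metric == "norm_modularity":
        return prof.normalized["modularity"]
    if metric == "small_worldness":
        return prof.small_worldness
    raise KeyError(metric)


def run_graph_comparison(cohort: Cohort, config: AnalysisConfig, profiles=None) -> dict:
    """Graph-metric group comparison and metric-behavior correlations.

    Globals (null-normalized where applicable) are compared with one-way
    ANOVA; local metrics per node with ANOVA + Bonferroni over the node
    count; the normalized rich-club curve per degree threshold k with
    Bonferroni over the number of k values; and each global metric is
    correlated with each behavioral variable within groups and pooled
    (Pearson, or Spearman for variables designated nonparametric).
    """
    if profiles is None:
        profiles = _subject_profiles(cohort, config)
    g1, g2 = cohort.group_names
    i1, i2 = cohort.group_indices(g1), cohort.group_indices(g2)

    global_table = []
    global_values = {}
    for metric in GLOBAL_METRICS:
        vals = np.array([_global_value(p, metric) for p in profiles])
        global_values[metric] = vals
        tr = one_way_anova([vals[i1], vals[i2]])
        global_table.append({"metric": metric, **_tr_dict(tr, "none")})

    local_tables = {}
    n_nodes = cohort.n_nodes
    for metric in LOCAL_METRICS:
        mat = np.stack([getattr(p, metric) for p in profiles])  # (subj, node)
        stats, ps = [], []
        for node in range(n_nodes):
            v = mat[:, node]
            try:
                tr = one_way_anova([v[i1], v[i2]])
                stats.append(tr.statistic)
                ps.append(tr.p_value)
            except ValueError:  # constant metric at this node
                stats.append(np.nan)
                ps.append(np.nan)
        ps = np.asarray(ps)
        valid = np.isfinite(ps)
        p_adj = np.full(n_nodes, np.nan)
        p_adj[valid] = bonferroni_adjust(ps[valid], m=n_nodes)
        local_tables[metric] = pd.DataFrame(
            {
                "node": range(n_nodes),
                "label": cohort.node_labels,
                "F": stats,
                "p": ps,
                "p_bonferroni": p_adj,
            }
        )

    # rich club per degree threshold k (only k defined in every subject)
    k_common = sorted(
        set.intersection(
            *[
                {k for k, v in p.normalized["rich_club"].items() if np.isfinite(v)}
                for p in profiles
            ]
        )
    )
    rich_rows = []
    if k_common:
        phi = np.array(
            [[p.normalized["rich_club"][k] for k in k_common] for p in profiles]
        )
        for col, k in enumerate(k_common):
            tr = one_way_anova([phi[i1, col], phi[i2, col]])
            rich_rows.append(
                {
                    "k": k,
                    **_tr_dict(
                        tr, "bonferroni_over_k",
                        p_adj=bonferroni_adjust([tr.p_value], m=len(k_common))[0],
                    ),
                }
            )
        avg_phi = phi.mean(axis=1)
        avg_tr = one_way_anova([avg_phi[i1], avg_phi[i2]])
        rich_avg = _tr_dict(avg_tr, "none")
    else:
        rich_avg = None

    correlations = []
    for metric in GLOBAL_METRICS:
        vals = global_values[metric]
        for var, desig in config.behavioral_variables.items():
            method = "spearman" if desig == "nonparametric" else "pearson"
            beh = np.asarray(cohort.behavior[var], dtype=float)
            for scope, idx in (("pooled", None), (g1, i1), (g2, i2)):
                v = vals if idx is None else vals[idx]
                b = beh if idx is None else beh[idx]
                try:
                    tr = correlate(v, b, method=method)
                except ValueError:
                    continue
                correlations.append(
                    {
                        "metric": metric,
                        "behavior": var,
                        "scope": scope,
                        **_tr_dict(tr, "none"),
                    }
                )

    return {
        "global_comparison": global_table,
        "local_comparison": {m: _df_records(df) for m, df in local_tables.items()},
        "rich_club_comparison": {"per_k": rich_rows, "average": rich_avg},
        "metric_behavior_correlations": correlations,
        "_local_tables": local_tables,
        "_profiles": profiles,
    }


# ---------------------------------------------------------------------------
# stage 5: outlier sensitivity re-run
# ---------------------------------------------------------------------------

def run_sensitivity_rerun(
    cohort: Cohort, config: AnalysisConfig, base_result: NBSResult
) -> dict:
    """Drop control-group edge outliers over significant components and re-run.

    Outliers are control subjects deviating more than ``outlier_sd_factor``
    group SDs on at least ``outlier_min_edges`` edges of the significant
    components.  The report gives the flagged subjects, the re-run NBS and
    the edge-set overlap (Jaccard) between original and re-run significant
    components.
    """
    sig = base_result.significant_components(config.alpha)
    if not sig:
        raise ValueError("base result has no significant components")
    edges = sorted({e for c in sig for e in c.edges})
    control = cohort.group_names[1]
    outliers = detect_edge_outliers(
        cohort,
        control,
        edges,
        sd_factor=config.outlier_sd_factor,
        min_edges=config.outlier_min_edges,
    )
    keep = [s for s in cohort.subject_ids if s not in outliers]
    n_control_left = sum(
        1 for s, g in zip(cohort.subject_ids, cohort.groups)
        if s in keep and g == control
    )
    if n_control_left < 2:
        raise ValueError("sensitivity re-run would leave < 2 control subjects")
    reduced = cohort.subset(keep)
    model = NBS(
        reduced,
        design=base_result.config.design,
        direction=base_result.config.direction,
        thresholds=base_result.config.thresholds,
        size_measure=base_result.config.size_measure,
        alpha=config.alpha,
        intensity_excess=base_result.config.intensity_excess,
    )
    rerun = model.fit(
        n_permutations=base_result.n_permutations, seed=base_result.seed
    )
    rerun_edges = {
        e for c in rerun.significant_components(config.alpha) for e in c.edges
    }
    overlap = recovery_score(rerun_edges, set(edges))
    return {
        "outliers_removed": sorted(outliers),
        "n_subjects_rerun": reduced.n_subjects,
        "original_significant_edges": len(edges),
        "rerun_significant_edges": len(rerun_edges),
        "edge_overlap_jaccard": overlap,
        "rerun": _nbs_section(reduced, rerun, config.alpha),
    }


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

def _strip_private(obj):
    if isinstance(obj, dict):
        return {
            k: _strip_private(v) for k, v in obj.items() if not k.startswith("_")
        }
    if isinstance(obj, (list, tuple)):
        return [_strip_private(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def full_report(config: AnalysisConfig, cohort: Cohort = None) -> StudyReport:
    """Run the whole study: characteristics, NBS, graph comparison, sensitivity.

    Outputs under ``config.output_dir``: ``report.json``, TSV tables, edge
    lists of significant components, and ``run.log``.  Any stage failure is
    recorded in ``report.errors`` with its stage name; later stages still
    run where possible.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report = StudyReport(config=config)
    try:
        if cohort is None:
            if config.manifest_path is None:
                raise ValueError("no cohort and no manifest_path configured")
            cohort = load_cohort(config.manifest_path)
        cohort = group_threshold(cohort, config.min_mean_weight)
        logger.info(
            "cohort: %d subjects, %d nodes, %d masked edges",
            cohort.n_subjects, cohort.n_nodes, len(cohort.masked_edges()[0]),
        )
        report.streamline_screening = total_streamline_report(cohort)

        def stage(name, fn, *args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
                logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
                return out
            except Exception as exc:  # record and continue
                logger.error("stage %s failed: %s", name, exc)
                report.errors.append({"stage": name, "error": str(exc)})
                return None

        report.characteristics = stage(
            "characteristics", run_cohort_characteristics, cohort, config
        )
        report.group_nbs = stage("group_nbs", run_group_nbs, cohort, config)
        report.behavior_nbs = {}
        for var in config.behavioral_variables:
            section = stage(
                f"behavior_nbs[{var}]", run_behavior_nbs, cohort, config, var
            )
            if section is not None:
                report.behavior_nbs[var] = section
        report.graph = stage("graph", run_graph_comparison, cohort, config)

        base = None
        if report.group_nbs:
            base = report.group_nbs.get("group1_less", {}).get("_result")
        if base is not None and base.significant_components(config.alpha):
            report.sensitivity = stage(
                "sensitivity", run_sensitivity_rerun, cohort, config, base
            )
        _write_outputs(report, cohort, config)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report


def _write_outputs(report: StudyReport, cohort: Cohort, config: AnalysisConfig):
    out = config.output_dir
    payload = _strip_private(report.to_dict())
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=1, allow_nan=True)
    if report.characteristics is not None:
        report.characteristics.to_csv(
            os.path.join(out, "characteristics.tsv"), sep="\t", index=False
        )
    if report.graph is not None:
        for metric, df in report.graph.get("_local_tables", {}).items():
            df.to_csv(
                os.path.join(out, f"local_{metric}.tsv"), sep="\t", index=False
            )
    # edge lists of significant components
    if report.group_nbs:
        for direction, section in report.group_nbs.items():
            result = section.get("_result")
            if result is None:
                continue
            for thr, comps in result.components.items():
                for rank, comp in enumerate(
                    (c for c in comps if c.p_fwe < config.alpha), 1
                ):
                    rows = [
                        {
                            "node_i_label": cohort.node_labels[i],
                            "node_j_label": cohort.node_labels[j],
                            "statistic": s,
                        }
                        for (i, j), s in zip(comp.edges, comp.edge_stats)
                    ]
                    pd.DataFrame(rows).to_csv(
                        os.path.join(
                            out,
                            f"component_{direction}_t{thr:g}_{rank}.tsv",
                        ),
                        sep="\t",
                        index=False,
                    )


# ---------------------------------------------------------------------------
# report schema validation
# ---------------------------------------------------------------------------

REPORT_REQUIRED_KEYS = {
    "provenance": dict,
    "characteristics": (list, type(None)),
    "group_nbs": (dict, type(None)),
    "behavior_nbs": (dict, type(None)),
    "graph": (dict, type(None)),
    "sensitivity": (dict, type(None)),
    "errors": list,
}


def validate_report(payload: dict) -> None:
    """Check report.json structure; raises ValueError on violations."""
    for key, typ in REPORT_REQUIRED_KEYS.items():
        if key not in payload:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(payload[key], typ):
            raise ValueError(f"report key {key!r} has wrong type")
    prov = payload["provenance"]
    for key in ("package_version", "seed", "config"):
        if key not in prov:
            raise ValueError(f"provenance missing {key!r}")
    if payload["group_nbs"]:
        for direction, section in payload["group_nbs"].items():
            if "thresholds" not in section:
                raise ValueError(f"NBS section {direction!r} missing thresholds")
            for thr, tsec in section["thresholds"].items():
                for comp in tsec["components"]:
                    for k in ("extent", "intensity", "p_fwe"):
                        if k not in comp:
                            raise ValueError(f"component missing {k!r}")
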