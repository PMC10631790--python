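"""Containers and plain-text I/O for weighted structural connectomes.

A connectome here is a symmetric nonnegative weighted adjacency matrix over a
fixed brain parcellation (e.g. 164 Destrieux + subcortical parcels, or 200
Schaefer parcels + 14 subcortical structures).  Edge weights are on a
streamline-count scale: two parcels are connected when at least one
tractography streamline terminates in both, and the weight is the (possibly
density-corrected, hence non-integer) streamline count.

A :class:`Cohort` bundles the per-subject connectomes with group labels, a
behavioral score table and a symmetric boolean *edge mask* selecting the
edges that enter group analysis.  The mask is populated by
:func:`group_threshold`, which removes connections that are weak on average
across all subjects and therefore likely spurious.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeMatrix",
    "Cohort",
    "BEHAVIOR_COLUMNS",
    "canonical_edge",
    "read_connectome",
    "write_connectome",
    "read_node_labels",
    "load_cohort",
    "save_cohort",
    "group_threshold",
    "detect_edge_outliers",
    "total_streamline_report",
]

#: Behavioral score columns expected in a cohort manifest.
BEHAVIOR_COLUMNS = (
    "inattention",
    "hyperactivity_impulsivity",
    "omission_errors",
    "commission_errors",
)

#: Default relative symmetry tolerance for matrices read from text.
SYMMETRY_RTOL = 1e-9


def canonical_edge(i: int, j: int) -> tuple[int, int]:
    """Return the canonical (low, high) form of an undirected edge."""
    if i == j:
        raise ValueError(f"self-loop ({i}, {j}) is not a valid edge")
    return (int(i), int(j)) if i < j else (int(j), int(i))


class ConnectomeMatrix:
    """One subject's symmetric, nonnegative weighted adjacency matrix.

    Parameters
    ----------
    weights : (n, n) array_like
        Symmetric nonnegative weights with a zero diagonal.  Asymmetry within
        ``symmetry_rtol * max(weights)`` (text round-off) is symmetrized by
        averaging; anything larger is an error.
    labels : sequence of str, optional
        Node labels, unique, length ``n``.  Defaults to ``node_000`` style
        names.
    """

    __slots__ = ("weights", "labels")

    def __init__(self, weights, labels=None, *, symmetry_rtol: float = SYMMETRY_RTOL):
        w = np.array(weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite values")
        if np.any(w < 0):
            raise ValueError("negative weight in connectome matrix")
        wmax = w.max() if w.size else 0.0
        tol = symmetry_rtol * max(wmax, 1.0)
        asym = np.abs(w - w.T).max() if w.size else 0.0
        if asym > tol:
            raise ValueError(
                f"matrix asymmetry {asym:.3g} exceeds tolerance {tol:.3g}"
            )
        if asym > 0:
            w = (w + w.T) / 2.0
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal entries must be zero (no self-connections)")
        n = w.shape[0]
        if labels is None:
            labels = [f"node_{i:03d}" for i in range(n)]
        labels = [str(x) for x in labels]
        if len(labels) != n:
            raise ValueError(f"{len(labels)} labels for {n} nodes")
        if len(set(labels)) != n:
            raise ValueError("node labels must be unique")
        self.weights = w
        self.labels = labels

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def edges(self):
        """Canonical (i, j) pairs, i < j, with nonzero weight."""
        iu, ju = np.nonzero(np.triu(self.weights, 1))
        return list(zip(iu.tolist(), ju.tolist()))

    def edge_weights(self) -> dict[tuple[int, int], float]:
        return {e: float(self.weights[e]) for e in self.edges()}

    def total_streamlines(self) -> float:
        """Sum of edge weights (each undirected edge counted once)."""
        return float(np.triu(self.weights, 1).sum())

    def copy(self) -> "ConnectomeMatrix":
        return ConnectomeMatrix(self.weights.copy(), list(self.labels))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectomeMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.weights, other.weights
        )

    def __repr__(self) -> str:
        return (
            f"<ConnectomeMatrix n_nodes={self.n_nodes} "
            f"n_edges={len(self.edges())}>"
        )


@dataclass
class Cohort:
    """An ordered set of subjects with connectomes, groups and behavior.

    Attributes
    ----------
    subject_ids : list of str
    groups : list of str
        Group label per subject; exactly two distinct labels.
    connectomes : list of ConnectomeMatrix
        All sharing node count and label order.
    behavior : pandas.DataFrame
        Indexed by subject id; missing values are NaN.
    edge_mask : (n, n) bool ndarray
        Symmetric, False diagonal; True marks analyzable edges.
    """

    subject_ids: list
    groups: list
    connectomes: list
    behavior: pd.DataFrame
    edge_mask: np.ndarray = field(default=None)

    def __post_init__(self):
        n_subj = len(self.subject_ids)
        if n_subj == 0:
            raise ValueError("empty cohort")
        if len(set(self.subject_ids)) != n_subj:
            raise ValueError("duplicate subject_id in cohort")
        if len(self.groups) != n_subj or len(self.connectomes) != n_subj:
            raise ValueError("subject_ids, groups and connectomes must align")
        labels0 = self.connectomes[0].labels
        for sid, c in zip(self.subject_ids, self.connectomes):
            if c.labels != labels0:
                raise ValueError(
                    f"subject {sid!r} node labels differ from the cohort's"
                )
        if len(self.group_names) != 2:
            raise ValueError(
                f"expected exactly two group labels, got {self.group_names}"
            )
        if self.edge_mask is None:
            n = self.n_nodes
            self.edge_mask = ~np.eye(n, dtype=bool)
        self.edge_mask = np.asarray(self.edge_mask, dtype=bool)
        if self.edge_mask.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("edge_mask shape mismatch")
        if not np.array_equal(self.edge_mask, self.edge_mask.T):
            raise ValueError("edge_mask must be symmetric")
        if np.any(np.diag(self.edge_mask)):
            raise ValueError("edge_mask diagonal must be False")
        self.behavior = self.behavior.reindex(self.subject_ids)

    # -- basic structure ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_nodes(self) -> int:
        return self.connectomes[0].n_nodes

    @property
    def node_labels(self) -> list:
        return self.connectomes[0].labels

    @property
    def group_names(self) -> list:
        """Distinct group labels in order of first appearance."""
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def group_indices(self, group) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.groups, dtype=object) == group)
        if idx.size == 0:
            raise ValueError(f"no subjects in group {group!r}")
        return idx

    def weight_stack(self) -> np.ndarray:
        """(n_subjects, n_nodes, n_nodes) array of all weight matrices."""
        return np.stack([c.weights for c in self.connectomes])

    def masked_edges(self):
        """Masked edges as (iu, ju) index arrays over the upper triangle."""
        triu_mask = np.triu(self.edge_mask, 1)
        iu, ju = np.nonzero(triu_mask)
        return iu, ju

    def edge_data_matrix(self):
        """Per-subject weights over masked edges.

        Returns
        -------
        X : (n_subjects, n_edges) ndarray
        iu, ju : index arrays giving each column's edge endpoints.
        """
        iu, ju = self.masked_edges()
        X = self.weight_stack()[:, iu, ju]
        return X, iu, ju

    def subset(self, keep_ids) -> "Cohort":
        """Cohort restricted to ``keep_ids`` (order preserved)."""
        keep = set(keep_ids)
        sel = [i for i, s in enumerate(self.subject_ids) if s in keep]
        if not sel:
            raise ValueError("subset would produce an empty cohort")
        return Cohort(
            subject_ids=[self.subject_ids[i] for i in sel],
            groups=[self.groups[i] for i in sel],
            connectomes=[self.connectomes[i] for i in sel],
            behavior=self.behavior.iloc[sel].copy(),
            edge_mask=self.edge_mask.copy(),
        )

    def with_mask(self, mask: np.ndarray) -> "Cohort":
        return replace(self, edge_mask=np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# file formats: TSV square matrices, TSV manifests
# ---------------------------------------------------------------------------

def _is_numeric_row(tokens) -> bool:
    try:
        [float(t) for t in tokens]
        return True
    except ValueError:
        return False


def read_connectome(path, labels_path=None) -> ConnectomeMatrix:
    """Read a whitespace/tab-delimited square weight matrix.

    The first row may be a header of node labels (detected by being
    non-numeric).  ``labels_path`` optionally points to a node-label TSV with
    columns ``index, label[, hemisphere, structure_class]`` and overrides any
    header labels.
    """
    with open(path) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"{path}: empty connectome file")
    labels = None
    if not _is_numeric_row(rows[0]):
        labels = rows[0]
        rows = rows[1:]
    try:
        w = np.array([[float(t) for t in r] for r in rows])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric matrix entry ({exc})") from None
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"{path}: matrix is not square (shape {w.shape})")
    if labels_path is not None:
        labels = read_node_labels(labels_path)
    if labels is not None and len(labels) != w.shape[0]:
        raise ValueError(
            f"{path}: {len(labels)} labels for {w.shape[0]} nodes"
        )
    return ConnectomeMatrix(w, labels)


def write_connectome(c: ConnectomeMatrix, path) -> None:
    """Write a connectome as TSV with a label header row.

    Floats are formatted with ``%.17g`` so that read -> write -> read
    round-trips bit-identically.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(c.labels) + "\n")
        for row in c.weights:
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def read_node_labels(path) -> list:
    """Node-label table: TSV with columns index, label[, hemisphere, class]."""
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns or "index" not in df.columns:
        raise ValueError(f"{path}: node-label table needs 'index' and 'label'")
    df = df.sort_values("index")
    return [str(x) for x in df["label"]]


def load_cohort(manifest_path) -> Cohort:
    """Load a cohort from a TSV manifest.

    The manifest has columns ``subject_id, group, connectome_path`` plus the
    behavioral columns of :data:`BEHAVIOR_COLUMNS`; empty cells are missing
    values.  Connectome paths are resolved relative to the manifest.
    """
    manifest_path = os.fspath(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "group", "connectome_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r} in manifest")
    base = os.path.dirname(os.path.abspath(manifest_path))
    connectomes = []
    for p in df["connectome_path"]:
        full = p if os.path.isabs(p) else os.path.join(base, p)
        connectomes.append(read_connectome(full))
    n_nodes = {c.n_nodes for c in connectomes}
    if len(n_nodes) > 1:
        raise ValueError(f"mixed node counts across subjects: {sorted(n_nodes)}")
    behavior_cols = [c for c in BEHAVIOR_COLUMNS if c in df.columns]
    behavior = df.set_index("subject_id")[behavior_cols].astype(float)
    return Cohort(
        subject_ids=df["subject_id"].tolist(),
        groups=df["group"].tolist(),
        connectomes=connectomes,
        behavior=behavior,
    )


def save_cohort(cohort: Cohort, directory) -> str:
    """Write per-subject matrices plus a manifest TSV; returns manifest path."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for sid, grp, c in zip(cohort.subject_ids, cohort.groups, cohort.connectomes):
        fname = f"{sid}.tsv"
        write_connectome(c, os.path.join(directory, fname))
        row = {"subject_id": sid, "group": grp, "connectome_path": fname}
        for col in cohort.behavior.columns:
            val = cohort.behavior.loc[sid, col]
            row[col] = "" if pd.isna(val) else val
        rows.append(row)
    manifest = os.path.join(directory, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# group-level edge selection and outlier screening
# ---------------------------------------------------------------------------

def group_threshold(cohort: Cohort, min_mean_weight: float = 10.0) -> Cohort:
    """Build the analyzable-edge mask by group-level thresholding.

    An edge is retained when its mean weight across *all* subjects is at
    least ``min_mean_weight`` (strict ``<`` removes; a mean of exactly the
    threshold is kept) and at least one subject has a nonzero weight there —
    a pair of parcels that no streamline ever connects is not an edge.
    Weights themselves are untouched; only the mask changes.

    The default of 10 reflects the convention of removing connections with
    fewer than 10 streamlines on average, which suppresses spurious
    tractography connections.
    """
    if min_mean_weight < 0:
        raise ValueError("min_mean_weight must be nonnegative")
    stack = cohort.weight_stack()
    mean_w = stack.mean(axis=0)
    any_nonzero = (stack > 0).any(axis=0)
    mask = (mean_w >= min_mean_weight) & any_nonzero
    np.fill_diagonal(mask, False)
    mask &= mask.T  # weights are symmetric so this is a no-op; keep invariant
    return cohort.with_mask(mask)


def detect_edge_outliers(
    cohort: Cohort,
    group,
    edge_set,
    sd_factor: float = 2.0,
    min_edges: int = 2,
) -> set:
    """Subjects of ``group`` deviating > ``sd_factor`` SD on >= ``min_edges`` edges.

    Per edge in ``edge_set``, the mean and sample SD (ddof=1) are computed
    over the named group *including* each candidate subject.  A subject is
    flagged when its absolute deviation from the group mean exceeds
    ``sd_factor`` SDs on at least ``min_edges`` of the edges.  Edges with
    zero SD (homogeneous group) can never be exceeded.

    This is the screening rule used for outlier-sensitivity re-analysis of
    significant subnetworks.
    """
    edges = [canonical_edge(i, j) for i, j in edge_set]
    if not edges:
        raise ValueError("empty edge_set")
    for e in edges:
        if not cohort.edge_mask[e]:
            raise ValueError(f"edge {e} is not in the cohort edge mask")
    idx = cohort.group_indices(group)
    if idx.size < 2:
        raise ValueError(f"group {group!r} too small for SD screening")
    iu = np.array([e[0] for e in edges])
    ju = np.array([e[1] for e in edges])
    vals = cohort.weight_stack()[idx][:, iu, ju]
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        exceed = np.abs(vals - mean) > sd_factor * sd
    exceed[:, sd == 0] = False
    counts = exceed.sum(axis=1)
    return {
        cohort.subject_ids[i]
        for i, c in zip(idx.tolist(), counts.tolist())
        if c >= min_edges
    }


def total_streamline_report(cohort: Cohort) -> pd.DataFrame:
    """Per-subject total streamline counts with cohort z-scores.

    Screening report only: unusually high totals (e.g. |z| > 3) are worth a
    manual look, but no subject is excluded automatically.
    """
    totals = np.array([c.total_streamlines() for c in cohort.connectomes])
    z = (totals - totals.mean()) / totals.std(ddof=1) if len(totals) > 1 else totals * 0
    return pd.DataFrame(
        {
            "subject_id": cohort.subject_ids,
            "group": cohort.groups,
            "total_streamlines": totals,
            "zscore": z,
        }
    )
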