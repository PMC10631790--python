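"""Minimal plotting helpers (matplotlib imported lazily).

These serve quick inspection of fitted results: the permutation null of the
max component size, and group-split network connectivity distributions.
Brain-surface rendering is out of scope.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_null_distribution", "plot_network_connectivity"]


def plot_null_distribution(result, threshold=None, ax=None):
    """Histogram of the null max component size with observed components marked."""
    import matplotlib.pyplot as plt

    cfg = result.config
    thr = cfg.thresholds[0] if threshold is None else threshold
    if ax is None:
        _, ax = plt.subplots()
    null = result.null_max_sizes[thr][cfg.size_measure]
    ax.hist(null, bins=30, color="0.7", edgecolor="0.4")
    for comp in result.components.get(thr, []):
        from .nbs import component_size

        ax.axvline(
            component_size(comp, cfg.size_measure),
            color="crimson",
            linestyle="--",
            label=f"observed (p={result.format_p(comp.p_fwe)})",
        )
    ax.set_xlabel(f"max component {cfg.size_measure} (threshold {thr:g})")
    ax.set_ylabel("permutations")
    if result.components.get(thr):
        ax.legend()
    return ax


def plot_network_connectivity(cohort, component, ax=None):
    """Strip plot of per-subject mean connectivity in a component, by group."""
    import matplotlib.pyplot as plt

    from .nbs import network_mean_connectivity

    net = network_mean_connectivity(cohort, component)
    if ax is None:
        _, ax = plt.subplots()
    rng = np.random.default_rng(0)
    for pos, grp in enumerate(cohort.group_names):
        idx = cohort.group_indices(grp)
        x = pos + rng.uniform(-0.12, 0.12, idx.size)
        ax.plot(x, net[idx], "o", alpha=0.6, label=grp)
        ax.hlines(net[idx].mean(), pos - 0.25, pos + 0.25, color="k")
    ax.set_xticks(range(len(cohort.group_names)), cohort.group_names)
    ax.set_ylabel("network mean edge weight")
    return ax
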