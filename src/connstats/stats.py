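"""Univariate statistics used throughout the cohort analysis.

All tests return a :class:`TestResult`.  Conventions match common
statistical software: two-sample t statistics use the group2-minus-group1
sign (so for a patient-vs-control table the statistic is control minus
patient), the chi-square test of association carries no continuity
correction, Pearson/Spearman p values come from the exact t transform with
``n - 2`` degrees of freedom, and the Mann-Whitney U uses midranks with the
tie-corrected normal approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "t_test_from_summary",
    "t_test",
    "welch_df",
    "chi_square_association",
    "mann_whitney_u",
    "correlate",
    "r_to_t",
    "t_tail_probability",
    "cohens_d",
    "one_way_anova",
    "bonferroni_adjust",
    "count_node_pairs",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with degrees of freedom and its p value."""

    statistic: float
    df: object  # float, or (df1, df2) for F
    p_value: float
    tail: str = "two"
    name: str = ""
    estimate: float = None  # e.g. the correlation coefficient

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p value {self.p_value} outside [0, 1]")


def _two_sample_t(m1, s1, n1, m2, s2, n2, variant):
    if s1 <= 0 or s2 <= 0:
        raise ValueError("zero or negative sample SD")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if variant == "pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    elif variant == "welch":
        se = math.sqrt(s1**2 / n1 + s2**2 / n2)
        df = welch_df(s1, n1, s2, n2)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se == 0:
        raise ValueError("zero standard error")
    return (m2 - m1) / se, df


def t_test_from_summary(m1, s1, n1, m2, s2, n2, variant="pooled") -> TestResult:
    """Two-sample t test from group means/SDs/sizes.

    Sign convention: statistic = (m2 - m1) / SE, i.e. group 2 minus group 1.
    With patients as group 1 and controls as group 2, elevated patient
    scores give negative t.
    """
    t, df = _two_sample_t(m1, s1, n1, m2, s2, n2, variant)
    p = 2 * t_tail_probability(abs(t), df)
    return TestResult(t, df, min(p, 1.0), tail="two", name=f"t_{variant}")


def t_test(x, y, variant="pooled", tail="two") -> TestResult:
    """Two-sample t test on data vectors; equals the summary-statistic route.

    ``tail='one'`` gives the upper-tail probability of the signed statistic
    (testing mean(y) > mean(x) under the group2-minus-group1 convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df = _two_sample_t(
        x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), variant
    )
    if tail == "one":
        p = t_tail_probability(t, df)
    else:
        p = min(2 * t_tail_probability(abs(t), df), 1.0)
    return TestResult(t, df, p, tail=tail, name=f"t_{variant}")


def welch_df(s1, n1, s2, n2) -> float:
    """Welch-Satterthwaite approximate degrees of freedom."""
    v1 = s1**2 / n1
    v2 = s2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def chi_square_association(table) -> TestResult:
    """Pearson chi-square test of association, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if np.any(obs < 0):
        raise ValueError("negative cell count")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero margin in contingency table")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if df == 0:
        raise ValueError("degenerate table (single row or column)")
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, df, p, tail="two", name="chi_square")


def mann_whitney_u(x, y, tail="two") -> TestResult:
    """Mann-Whitney U with midrank ties and tie-corrected normal p.

    The reported U is the x-based statistic ``#{x_i > y_j} + 0.5 #{ties}``;
    complete separation with all x below all y gives U = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2
    n = n1 + n2
    mu = n1 * n2 / 2
    # tie correction to the variance
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var == 0:
        return TestResult(float(u), float("nan"), 1.0, tail=tail, name="mann_whitney_u")
    z = (u - mu) / math.sqrt(var)
    if tail == "one":
        p = float(sps.norm.sf(z))
    else:
        p = float(2 * sps.norm.sf(abs(z)))
    return TestResult(float(u), float("nan"), min(p, 1.0), tail=tail, name="mann_whitney_u")


def correlate(x, y, method="pearson") -> TestResult:
    """Pearson r or Spearman rho with p from the t transform (df = n - 2).

    Missing values are removed pairwise; the reduced n drives the df.
    Spearman uses midranks, then the Pearson machinery on the ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in correlation input")
    r = float(np.dot(x - x.mean(), y - y.mean()) / ((n - 1) * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        return TestResult(float("inf") * np.sign(r), df, 0.0, name=method, estimate=r)
    t = r_to_t(r, n)
    p = min(2 * t_tail_probability(abs(t), df), 1.0)
    return TestResult(t, df, p, tail="two", name=method, estimate=r)


def r_to_t(r, n) -> float:
    """Map a correlation coefficient to its t statistic: r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1:
        raise ValueError("|r| = 1 gives an infinite statistic")
    return r * math.sqrt(n - 2) / math.sqrt(1 - r * r)


def r_of_t(t, n) -> float:
    """Inverse of :func:`r_to_t` on (-1, 1)."""
    if n < 3:
        raise ValueError("need n >= 3")
    return t / math.sqrt(n - 2 + t * t)


def t_tail_probability(t, df) -> float:
    """One-tailed upper-tail probability of Student's t."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(sps.t.sf(t, df))


def cohens_d(x, y) -> float:
    """Cohen's d: mean difference over the pooled SD (group1 minus group2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def one_way_anova(groups) -> TestResult:
    """One-way fixed-effects ANOVA; F with (k-1, N-k) degrees of freedom.

    For two groups, F equals the square of the pooled two-sample t.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = ns.sum()
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere")
    f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (df1, int(df2)), p, tail="one", name="anova_F")


def bonferroni_adjust(p_values, m=None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise.

    ``m`` defaults to the number of p values and must be at least that.
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be >= number of p values")
    return np.minimum(1.0, p * m)


def count_node_pairs(n: int) -> int:
    """Number of unordered node pairs: n(n-1)/2.  164 nodes -> 13,366."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n * (n - 1) // 2
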