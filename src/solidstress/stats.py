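"""Group comparisons and spatial-trend analysis.

Conventions follow the study design: results are summarized as
mean ± SEM, two-group comparisons use a two-tailed t-test with n ≥ 3
per group (Welch's unequal-variance form by default, Student's pooled
form as an option), multi-group comparisons use one-way ANOVA, and
anterior–posterior spatial trends are tested by OLS regression of an
index against position within fixed windows (defaults 0–1000,
1000–2250 and 2250–4250 µm from the anterior reference).  No
multiple-testing correction is applied by default; a Holm option is
available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

DEFAULT_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 1000.0), (1000.0, 2250.0), (2250.0, 4250.0))

MIN_GROUP_N = 3  # two-group tests require n >= 3 per group


@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    sem: float


@dataclass
class ComparisonResult:
    """Outcome of a t-test, ANOVA or slope test."""

    kind: str                     # "t" | "anova" | "slope"
    statistic: float
    p_value: float
    df: float
    groups: list[GroupStats] = field(default_factory=list)
    extras: dict = field(default_factory=dict)
    flagged: str | None = None


def _group_stats(label: str, x: np.ndarray) -> GroupStats:
    x = np.asarray(x, dtype=float)
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else np.nan
    return GroupStats(label=label, n=x.size, mean=float(x.mean()), sem=sem)


def compare_two_groups(
    a, b, method: str = "welch", labels: tuple[str, str] = ("a", "b")
) -> ComparisonResult:
    """Two-tailed two-sample t-test with mean ± SEM per group.

    ``method='welch'`` (default) does not assume equal variances;
    ``method='student'`` pools them.  Groups smaller than 3 are rejected.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < MIN_GROUP_N or b.size < MIN_GROUP_N:
        raise ValueError(f"two-group t-test requires n >= {MIN_GROUP_N} per group")
    if method not in ("welch", "student"):
        raise ValueError(f"unknown t-test method {method!r}")
    res = sps.ttest_ind(a, b, equal_var=(method == "student"))
    return ComparisonResult(
        kind="t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.df),
        groups=[_group_stats(labels[0], a), _group_stats(labels[1], b)],
        extras={"method": method},
    )


def compare_many_groups(groups, labels=None) -> ComparisonResult:
    """One-way ANOVA across ≥ 2 groups (n ≥ 3 each)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if any(g.size < MIN_GROUP_N for g in arrays):
        raise ValueError(f"ANOVA requires n >= {MIN_GROUP_N} per group")
    labels = labels or [f"g{i}" for i in range(len(arrays))]
    flagged = None
    within_var = sum(float(((g - g.mean()) ** 2).sum()) for g in arrays)
    means = [g.mean() for g in arrays]
    if within_var == 0 and np.ptp(means) == 0:
        # all values identical everywhere: F is 0/0; report no evidence
        stat, p, flagged = 0.0, 1.0, "degenerate: zero variance and equal means"
    else:
        res = sps.f_oneway(*arrays)
        stat, p = float(res.statistic), float(res.pvalue)
    n_tot = sum(g.size for g in arrays)
    return ComparisonResult(
        kind="anova",
        statistic=stat,
        p_value=p,
        df=float(len(arrays) - 1),
        groups=[_group_stats(l, g) for l, g in zip(labels, arrays)],
        extras={"df_within": n_tot - len(arrays)},
        flagged=flagged,
    )


def spatial_trend(
    table: pd.DataFrame,
    index_col: str,
    window: tuple[float, float],
    position_col: str = "position_ap",
) -> ComparisonResult:
    """OLS slope of an index against anterior–posterior position.

    Restricted to ``window`` = [lo, hi) µm; reports the slope, its
    standard error and the two-sided p-value for slope = 0.
    """
    lo, hi = window
    sub = table[(table[position_col] >= lo) & (table[position_col] < hi)].dropna(
        subset=[index_col, position_col]
    )
    if len(sub) < 3:
        raise ValueError(f"need >= 3 slices with position in [{lo}, {hi}) µm, have {len(sub)}")
    x = sm.add_constant(sub[position_col].to_numpy(dtype=float))
    fit = sm.OLS(sub[index_col].to_numpy(dtype=float), x).fit()
    return ComparisonResult(
        kind="slope",
        statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        df=float(fit.df_resid),
        groups=[_group_stats(f"[{lo:g},{hi:g})", sub[index_col].to_numpy(dtype=float))],
        extras={
            "slope": float(fit.params[1]),
            "slope_se": float(fit.bse[1]),
            "intercept": float(fit.params[0]),
            "window_um": [lo, hi],
            "n": int(len(sub)),
        },
    )


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
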