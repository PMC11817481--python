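"""Two-group statistical comparison of protein metrics.

The screened (disordered) set is compared with a background set metric
by metric, with both an unpaired Welch t-test and a two-sided
Mann–Whitney U test. No multiple-testing adjustment is applied by
default (the tests answer per-metric questions); Benjamini–Hochberg
adjusted q-values can be requested.

The Mann–Whitney p-value is exact (full enumeration of the U null
distribution) when both groups have at most ``EXACT_MW_MAX_N``
observations and the pooled data has no ties; otherwise the normal
approximation with tie correction and continuity correction is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    median: float
    sd: float  # sample sd (n-1 denominator); NaN when n == 1


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: GroupSummary
    group_b: GroupSummary
    welch_t: float
    welch_df: float
    t_pvalue: float
    mw_u: float
    mw_pvalue: float


def summarize(values) -> GroupSummary:
    """n, mean, median and sample sd of one group."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return GroupSummary(n=int(arr.size), mean=float(arr.mean()),
                        median=float(np.median(arr)), sd=sd)


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of the first group, p).

    U comes from midrank sums. With n_a, n_b <= 8 and no ties the p is
    exact by enumerating the null distribution of U; otherwise the
    normal approximation with tie and continuity corrections applies.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        # Complete degeneracy: no evidence of a shift either way.
        return a.size * b.size / 2.0, 1.0
    exact = (a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N
             and not _has_ties(pooled))
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def welch_t(a, b) -> tuple[float, float, float]:
    """Unpaired Welch t-test; returns (t, Welch–Satterthwaite df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), \
            float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    se_a, se_b = va / a.size, vb / b.size
    df = (se_a + se_b) ** 2 / (se_a ** 2 / (a.size - 1) + se_b ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def compare_metrics(table_a, table_b, metrics=None,
                    bh_adjust: bool = False) -> "pandas.DataFrame":  # noqa: F821
    """Compare every shared numeric column of two profile tables.

    Returns one row per metric with per-group summaries and both test
    results. ``metrics`` restricts the columns; a requested column
    missing from either table is an error naming it.
    """
    import pandas as pd

    numeric_a = set(table_a.select_dtypes("number").columns)
    numeric_b = set(table_b.select_dtypes("number").columns)
    if metrics is None:
        metrics = [c for c in table_a.columns
                   if c in numeric_a and c in numeric_b and c != "length"
                   and c != "n"]
    else:
        for col in metrics:
            for name, cols in (("first", table_a.columns), ("second", table_b.columns)):
                if col not in cols:
                    raise KeyError(f"metric {col!r} missing from {name} table")

    rows = []
    for metric in metrics:
        a = table_a[metric].to_numpy(dtype=float)
        b = table_b[metric].to_numpy(dtype=float)
        sa, sb = summarize(a), summarize(b)
        t, df, tp = welch_t(a, b)
        u, up = mann_whitney_u(a, b)
        rows.append({
            "metric": metric,
            "n_a": sa.n, "mean_a": sa.mean, "median_a": sa.median, "sd_a": sa.sd,
            "n_b": sb.n, "mean_b": sb.mean, "median_b": sb.median, "sd_b": sb.sd,
            "welch_t": t, "welch_df": df, "t_pvalue": tp,
            "mw_u": u, "mw_pvalue": up,
        })
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        for col in ("t_pvalue", "mw_pvalue"):
            out[col + "_bh"] = _benjamini_hochberg(out[col].to_numpy())
    return out


def _benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    m = pvalues.size
    order = np.argsort(pvalues)
    ranked = pvalues[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
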