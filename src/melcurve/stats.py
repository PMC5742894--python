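"""Nonparametric cohort comparison of fitted model parameters.

Cohorts are compared parameter-by-parameter with the Mann–Whitney U test
(exact enumeration p-value for small tie-free samples, normal
approximation with tie and continuity corrections otherwise); the
Kruskal–Wallis test handles more than two groups, and a paired Wilcoxon
signed-rank test is available though unused by the default pipeline.
Raw p-values are reported without multiple-testing correction.

Circular quantities (phase and DLMO clock times) are rank-tested on
their [0, 24) representatives; this is the convention of the motivating
analyses and carries the usual caveat that ranks near the midnight
wrap-around are not circular-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PARAMETER_COLUMNS",
    "GroupComparison",
    "cohort_medians",
    "truncate_2dp",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "compare_cohorts",
    "boxplot_summary",
    "SIGNIFICANCE_LEVEL",
]

#: the ten per-subject quantities compared between cohorts
PARAMETER_COLUMNS = [
    "b1", "b2", "b3", "b4", "b_max",
    "dlmo_on50", "dlmo_off50", "dlmo_on25", "dlmo_off25", "max_gamma",
]

SIGNIFICANCE_LEVEL = 0.05

#: largest n_a*n_b for which the exact enumeration p-value is used in auto mode
_EXACT_LIMIT = 400


@dataclass(frozen=True)
class GroupComparison:
    parameter_name: str
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def cohort_medians(values) -> float:
    """Sample median (midpoint of central order statistics for even n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot take the median of an empty cohort")
    return float(np.median(arr))


def truncate_2dp(x: float) -> float:
    """Truncate (not round) to two decimals, the tables' reporting rule."""
    return math.trunc(float(x) * 100.0) / 100.0


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return np.unique(pooled).size != pooled.size


def mann_whitney(a, b, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann–Whitney U test between two independent samples.

    ``mode``: ``"exact"`` (full enumeration of rank assignments),
    ``"normal-approx"`` (tie- and continuity-corrected), or ``"auto"``
    (exact when ``n_a * n_b <= 400`` and the pooled sample is tie-free).
    The reported U is the statistic of the first sample, computed by
    midrank summation; ``U(a,b) + U(b,a) = n_a * n_b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")

    ties = _has_ties(a, b)
    if mode == "auto":
        mode = "exact" if (a.size * b.size <= _EXACT_LIMIT and not ties) else "normal-approx"

    ranks = sps.rankdata(np.concatenate([a, b]))
    u_a = float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)

    if mode == "exact":
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        if not np.isfinite(p):  # zero variance after tie correction
            p = 1.0
    return GroupComparison(
        parameter_name="",
        median_a=cohort_medians(a),
        median_b=cohort_medians(b),
        u_statistic=u_a,
        p_value=min(p, 1.0),
        n_a=int(a.size),
        n_b=int(b.size),
        method=mode,
    )


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (statistic, two-sided p)."""
    res = sps.wilcoxon(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and chi-square p across >= 2 groups.

    All-tied input, where the tie correction annihilates the denominator,
    returns ``H = 0, p = 1`` by convention.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(
    fit_table_a: pd.DataFrame,
    fit_table_b: pd.DataFrame,
    parameters=PARAMETER_COLUMNS,
    mode: str = "auto",
) -> list[GroupComparison]:
    """One Mann–Whitney comparison per model parameter between two cohorts.

    Both tables must carry all requested parameter columns (one row per
    subject).  Returns full-precision medians; two-decimal table
    reporting uses `truncate_2dp`.
    """
    for name, tab in (("first", fit_table_a), ("second", fit_table_b)):
        if len(tab) == 0:
            raise ValueError(f"{name} cohort table is empty")
        missing = [c for c in parameters if c not in tab.columns]
        if missing:
            raise ValueError(f"{name} cohort table is missing columns: {missing}")
    out = []
    for col in parameters:
        res = mann_whitney(
            fit_table_a[col].to_numpy(float), fit_table_b[col].to_numpy(float), mode=mode
        )
        out.append(
            GroupComparison(
                parameter_name=col,
                median_a=res.median_a,
                median_b=res.median_b,
                u_statistic=res.u_statistic,
                p_value=res.p_value,
                n_a=res.n_a,
                n_b=res.n_b,
                method=res.method,
            )
        )
    return out


def comparison_frame(comparisons) -> pd.DataFrame:
    """Tabulate `GroupComparison` results (one row per parameter)."""
    return pd.DataFrame(
        {
            "parameter": [c.parameter_name for c in comparisons],
            "median_a": [c.median_a for c in comparisons],
            "median_b": [c.median_b for c in comparisons],
            "median_a_2dp": [truncate_2dp(c.median_a) for c in comparisons],
            "median_b_2dp": [truncate_2dp(c.median_b) for c in comparisons],
            "u_statistic": [c.u_statistic for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "significant": [c.significant for c in comparisons],
            "method": [c.method for c in comparisons],
        }
    )


def boxplot_summary(values) -> dict:
    """Five-number summary plus Tukey-fence outliers, for boxplot glue."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = arr[(arr >= lo) & (arr <= hi)]
    return {
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(v) for v in arr[(arr < lo) | (arr > hi)]],
    }
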