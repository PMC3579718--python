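"""Two-group inference over ROI metrics.

The study design is an unpaired two-tailed Student t-test with pooled
(homoscedastic) variance, df = n_A + n_B − 2, one raw p per ROI per
metric with no multiplicity correction (an optional Holm adjustment is
available but off by default).  Group descriptives use the sample (n−1)
standard deviation; the population SD appears only inside the voxel-wise
z-normalization — the two conventions are deliberately kept apart.
Significance is flagged at p <= alpha inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "t_pvalue",
    "unpaired_ttest",
    "compare_cohort",
    "comparisons_to_frame",
]


@dataclass
class GroupComparison:
    roi: str
    metric: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    df: int
    p_two_tailed: float
    significant: bool
    alpha: float
    degenerate: bool = False  # zero pooled variance with unequal means
    n_dropped: int = 0  # missing-value entries removed pairwise


def t_pvalue(t: float, df: float) -> float:
    """Two-tailed Student-t p value, p = 2·S(|t|; df)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not np.isfinite(t):
        raise ValueError("t statistic must be finite")
    return float(2.0 * stats.t.sf(abs(t), df))


def unpaired_ttest(
    values_a,
    values_b,
    roi: str = "",
    metric: str = "",
    alpha: float = 0.05,
) -> GroupComparison:
    """Pooled-variance unpaired two-tailed t-test.

    NaN entries (e.g. ROIs with no suprathreshold voxels in a subject)
    are dropped per group before testing; the number removed is reported.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    n_dropped = int(np.isnan(a).sum() + np.isnan(b).sum())
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            f"need >= 2 usable values per group, got {n_a} and {n_b}"
        )
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    df = n_a + n_b - 2
    pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    degenerate = False
    if pooled_var == 0:
        if mean_a == mean_b:
            raise ValueError("both groups constant and equal: t undefined")
        # all within-group variation vanished: report the limiting p -> 0
        t = math.inf if mean_a > mean_b else -math.inf
        p = 0.0
        degenerate = True
    else:
        se = math.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
        t = (mean_a - mean_b) / se
        p = t_pvalue(t, df)
    return GroupComparison(
        roi=roi,
        metric=metric,
        n_a=n_a,
        n_b=n_b,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        t_statistic=float(t),
        df=df,
        p_two_tailed=float(p),
        significant=bool(p <= alpha),
        alpha=alpha,
        degenerate=degenerate,
        n_dropped=n_dropped,
    )


def compare_cohort(
    roi_table: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    group_a: str = "control",
    group_b: str = "mutant",
    holm: bool = False,
) -> list[GroupComparison]:
    """One two-group test per ROI for one metric column.

    ``roi_table`` must carry columns ``roi``, ``group`` and the metric.
    Results are sorted by ROI name for determinism.  An ROI with fewer
    than two usable (non-missing) values in a group is reported with NaN
    statistics and ``significant=False`` rather than aborting the whole
    battery.  With ``holm=True`` the significance flags (not the p
    values) follow a Holm step-down adjustment across ROIs.
    """
    if metric not in roi_table.columns:
        raise KeyError(f"metric {metric!r} not in table columns {list(roi_table.columns)}")
    for g in (group_a, group_b):
        if g not in set(roi_table["group"]):
            raise ValueError(f"group {g!r} absent from table")
    results = []
    for roi in sorted(roi_table["roi"].unique()):
        sub = roi_table[roi_table["roi"] == roi]
        a = np.asarray(sub[sub["group"] == group_a][metric], dtype=float)
        b = np.asarray(sub[sub["group"] == group_b][metric], dtype=float)
        try:
            results.append(unpaired_ttest(a, b, roi=roi, metric=metric, alpha=alpha))
        except ValueError:
            # too few usable values, or both groups constant and equal:
            # record the battery entry as not computable
            n_a = int((~np.isnan(a)).sum())
            n_b = int((~np.isnan(b)).sum())
            results.append(
                GroupComparison(
                    roi=roi, metric=metric, n_a=n_a, n_b=n_b,
                    mean_a=math.nan, sd_a=math.nan, mean_b=math.nan, sd_b=math.nan,
                    t_statistic=math.nan, df=max(n_a + n_b - 2, 0),
                    p_two_tailed=math.nan, significant=False, alpha=alpha,
                    degenerate=True,
                    n_dropped=int(np.isnan(a).sum() + np.isnan(b).sum()),
                )
            )
    if holm:
        order = np.argsort([r.p_two_tailed for r in results])
        m = len(results)
        running_reject = True
        for rank, idx in enumerate(order):
            r = results[idx]
            adjusted_alpha = r.alpha / (m - rank)
            running_reject = running_reject and (r.p_two_tailed <= adjusted_alpha)
            r.significant = running_reject
    return results


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    cols = [
        "roi", "metric", "n_a", "n_b", "mean_a", "sd_a", "mean_b", "sd_b",
        "t_statistic", "df", "p_two_tailed", "significant", "alpha",
        "degenerate", "n_dropped",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results])
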