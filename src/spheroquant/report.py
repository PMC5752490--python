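"""Group comparisons and summary tables over per-spheroid measurements.

Wraps the standard battery of tests (two-sample and paired t, one-way ANOVA,
Wilcoxon signed-rank, Kruskal–Wallis) with a uniform result record; p-values
are reported raw (no multiple-testing correction is applied, and the result
labels them as unadjusted). Significance is flagged at α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonResult", "compare_groups", "summarize", "plot_group_summary"]

DESIGNS = ("t", "paired_t", "anova", "wilcoxon", "kruskal")


@dataclass
class ComparisonResult:
    metric: str
    design: str
    group_labels: list[str]
    group_means: list[float]
    group_sds: list[float]
    group_ns: list[int]
    statistic: float
    p_value: float
    alpha: float = 0.05
    adjusted: bool = False      # raw p-values, no multiple-testing correction

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_arrays(groups: dict[str, object]) -> tuple[list[str], list[np.ndarray]]:
    labels = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    return labels, arrs


def compare_groups(
    groups: dict[str, object],
    design: str = "t",
    metric: str = "value",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Compare per-spheroid values between conditions.

    ``design`` is one of ``t`` (two-sample Student t), ``paired_t``,
    ``anova`` (one-way), ``wilcoxon`` (paired signed-rank) or ``kruskal``.
    Paired designs require equal-length, matched groups. Degenerate paired
    data with a constant nonzero difference is reported as p = 0 (an exact
    shift); identical groups give statistic 0, p = 1.
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    labels, arrs = _as_arrays(groups)
    two_group = design in ("t", "paired_t", "wilcoxon")
    if two_group and len(arrs) != 2:
        raise ValueError(f"design {design!r} needs exactly 2 groups")
    if design in ("paired_t", "wilcoxon") and arrs[0].size != arrs[1].size:
        raise ValueError("paired design needs matched, equal-length groups")

    if design == "t":
        if np.array_equal(arrs[0], arrs[1]):
            stat, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(arrs[0], arrs[1], equal_var=True)
            stat, p = float(res.statistic), float(res.pvalue)
    elif design == "paired_t":
        diff = arrs[0] - arrs[1]
        if diff.size < 2:
            raise ValueError("paired t needs at least 2 pairs")
        if np.std(diff, ddof=1) == 0.0:
            # zero-variance constant shift: exact, off scipy's support
            stat = 0.0 if diff.mean() == 0 else math.copysign(math.inf, diff.mean())
            p = 1.0 if diff.mean() == 0 else 0.0
        else:
            res = stats.ttest_rel(arrs[0], arrs[1])
            stat, p = float(res.statistic), float(res.pvalue)
    elif design == "anova":
        if len(arrs) < 2:
            raise ValueError("ANOVA needs >= 2 groups")
        res = stats.f_oneway(*arrs)
        stat, p = float(res.statistic), float(res.pvalue)
    elif design == "wilcoxon":
        if np.array_equal(arrs[0], arrs[1]):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(arrs[0], arrs[1])
            stat, p = float(res.statistic), float(res.pvalue)
    else:  # kruskal
        if len(arrs) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        res = stats.kruskal(*arrs)
        stat, p = float(res.statistic), float(res.pvalue)

    return ComparisonResult(
        metric=metric,
        design=design,
        group_labels=labels,
        group_means=[float(a.mean()) for a in arrs],
        group_sds=[float(np.std(a, ddof=1)) if a.size > 1 else 0.0 for a in arrs],
        group_ns=[int(a.size) for a in arrs],
        statistic=stat,
        p_value=p,
        alpha=alpha,
    )


def summarize(table: pd.DataFrame, condition_col: str = "condition") -> pd.DataFrame:
    """Condition × metric summary of a per-spheroid table.

    Numeric columns get mean, SD and n per condition (single-row conditions
    report SD 0 with ``sd_undefined`` set); boolean columns additionally get
    the positive fraction. Rows are ordered deterministically by
    (condition, metric).
    """
    if len(table) == 0:
        raise ValueError("empty table")
    if condition_col not in table.columns:
        raise ValueError(f"missing {condition_col!r} column")
    rows = []
    metric_cols = [c for c in table.columns if c != condition_col]
    for cond, sub in table.groupby(condition_col, sort=True):
        for col in metric_cols:
            vals = sub[col]
            if vals.dtype == bool:
                rows.append(
                    {
                        "condition": cond,
                        "metric": col,
                        "n": int(vals.size),
                        "mean": float(vals.mean()),
                        "sd": float(vals.astype(float).std(ddof=1)) if vals.size > 1 else 0.0,
                        "sd_undefined": vals.size < 2,
                        "positive_fraction": float(vals.mean()),
                    }
                )
            elif np.issubdtype(vals.dtype, np.number):
                rows.append(
                    {
                        "condition": cond,
                        "metric": col,
                        "n": int(vals.size),
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                        "sd_undefined": vals.size < 2,
                        "positive_fraction": np.nan,
                    }
                )
    out = pd.DataFrame(rows).sort_values(["condition", "metric"], kind="stable")
    return out.reset_index(drop=True)


def plot_group_summary(summary: pd.DataFrame, metric: str, path=None):
    """Bar chart (mean ± SD) of one metric across conditions.

    Returns the matplotlib Figure; writes it to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["metric"] == metric]
    if len(sub) == 0:
        raise ValueError(f"metric {metric!r} not in summary")
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(sub["condition"].astype(str), sub["mean"], yerr=sub["sd"], capsize=3)
    ax.set_ylabel(metric)
    ax.set_xlabel("condition")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
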