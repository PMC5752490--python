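"""Growth-ratio analysis and subpopulation structure.

The growth ratio GR of a spheroid is the ratio of its sectional area after vs
before a treatment interval; a control population's mean ± SD GR defines
high-proliferating (HP, GR above the upper cutoff) and low-proliferating (LP,
GR below the lower cutoff) subpopulations, with the remainder "mid".
Correlation (Pearson) and k-means clustering (e.g. of GR against per-spheroid
estrogen-receptor FI) support the population-structure analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .quantify import CutoffRule

__all__ = [
    "GrowthRecord",
    "ClusterAssignment",
    "growth_ratio",
    "growth_table",
    "classify_growth",
    "relative_change",
    "pearson",
    "kmeans_cluster",
    "gr_histogram",
]

CLASSES = ("LP", "mid", "HP")


@dataclass
class GrowthRecord:
    spheroid_id: int | str
    area_before_um2: float
    area_after_um2: float
    gr: float
    percent_change: float
    growth_class: str | None = None


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # (n,), 0..k-1, ordered by first-feature center
    centers: np.ndarray           # (k, d), original (unstandardized) units
    inertia: float                # within-cluster sum of squares (z-scored space)


def growth_ratio(area_before: float, area_after: float) -> tuple[float, float]:
    """(GR, percent change) for one spheroid; both areas must be > 0."""
    if area_before <= 0 or area_after <= 0:
        raise ValueError("areas must be > 0")
    gr = area_after / area_before
    return gr, 100.0 * (gr - 1.0)


def growth_table(
    ids, areas_before, areas_after
) -> pd.DataFrame:
    """Per-spheroid growth table with gr and percent_change columns."""
    before = np.asarray(areas_before, dtype=float)
    after = np.asarray(areas_after, dtype=float)
    if np.any(before <= 0) or np.any(after <= 0):
        raise ValueError("areas must be > 0")
    gr = after / before
    return pd.DataFrame(
        {
            "spheroid_id": list(ids),
            "area_before_um2": before,
            "area_after_um2": after,
            "gr": gr,
            "percent_change": 100.0 * (gr - 1.0),
        }
    )


def classify_growth(
    records: pd.DataFrame, rule: CutoffRule
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each spheroid HP/mid/LP by its GR against control cutoffs.

    HP iff GR strictly above the upper cutoff, LP iff strictly below the
    lower; values at a cutoff are "mid". Returns the labelled table (copy)
    and a per-class summary (fraction, n, GR mean ± SD); the class fractions
    sum to 1.
    """
    if len(records) == 0:
        raise ValueError("empty record table")
    out = records.copy()
    gr = out["gr"].to_numpy(dtype=float)
    cls = np.where(gr > rule.upper, "HP", np.where(gr < rule.lower, "LP", "mid"))
    out["growth_class"] = cls
    rows = []
    for c in CLASSES:
        sel = gr[cls == c]
        rows.append(
            {
                "growth_class": c,
                "n": sel.size,
                "fraction": sel.size / gr.size,
                "gr_mean": sel.mean() if sel.size else np.nan,
                "gr_sd": np.std(sel, ddof=1) if sel.size > 1 else np.nan,
            }
        )
    return out, pd.DataFrame(rows)


def relative_change(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after`` (negative = increase)."""
    if before == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (before - after) / before


def pearson(x, y) -> float:
    """Product-moment correlation of two paired samples (n ≥ 3, finite)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input")
    return float(stats.pearsonr(x, y).statistic)


def kmeans_cluster(features, k: int, seed: int = 0) -> ClusterAssignment:
    """K-means (k-means++, Lloyd, n_init=10) on z-scored features.

    Features are standardized per column before clustering because GR (≈1)
    and FI (≈1–15 au) live on different scales; returned centers are mapped
    back to original units, and labels are relabelled so cluster centers are
    sorted ascending on the first feature (deterministic labelling).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1 or n < k:
        raise ValueError("need k >= 1 and n >= k")
    mu = X.mean(axis=0)
    sd = np.std(X, axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw_labels = km.fit_predict(Z)
    centers_z = km.cluster_centers_
    order = np.argsort(centers_z[:, 0], kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    centers = centers_z[order] * sd + mu
    return ClusterAssignment(labels=labels, centers=centers, inertia=float(km.inertia_))


def gr_histogram(gr_values, binning="fd") -> tuple[np.ndarray, np.ndarray]:
    """GR distribution histogram (counts, bin edges); Freedman–Diaconis default."""
    vals = np.asarray(gr_values, dtype=float)
    edges = np.histogram_bin_edges(vals, bins=binning)
    counts, edges = np.histogram(vals, bins=edges)
    return counts, edges
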