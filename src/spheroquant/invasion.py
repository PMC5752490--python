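"""Collective migration of matrix-embedded spheroids.

Spheroids embedded in a collagen matrix are imaged at two timepoints; the
migration distance of each spheroid is the Euclidean displacement of its ROI
centroid, d = √((X1−X2)² + (Y1−Y2)²), in µm. Per-condition summaries feed
the group-comparison machinery in :mod:`spheroquant.report`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import SpheroidROI

__all__ = ["MigrationRecord", "migration_distance", "invasion_summary"]


@dataclass
class MigrationRecord:
    spheroid_id: int | str
    x1_um: float
    y1_um: float
    x2_um: float
    y2_um: float
    distance_um: float
    elapsed_hours: float | None = None


def migration_distance(
    roi_before: SpheroidROI,
    roi_after: SpheroidROI,
    elapsed_hours: float | None = None,
) -> MigrationRecord:
    """Euclidean centroid displacement of one tracked spheroid, in µm.

    In the microchamber assay the two ROIs share a chamber; in collagen the
    pairing comes from tracking, so only an explicit chamber mismatch is
    rejected.
    """
    if (
        roi_before.chamber is not None
        and roi_after.chamber is not None
        and roi_before.chamber != roi_after.chamber
    ):
        raise ValueError("ROIs are not tracked to the same spheroid")
    x1, y1 = roi_before.centroid_um
    x2, y2 = roi_after.centroid_um
    d = math.hypot(x1 - x2, y1 - y2)
    sid = roi_before.chamber if roi_before.chamber is not None else roi_before.id
    return MigrationRecord(sid, x1, y1, x2, y2, d, elapsed_hours)


def invasion_summary(
    records_by_condition: dict[str, list], bins: int | str = "auto"
) -> tuple[pd.DataFrame, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Per-condition migration-distance summary and distance histograms.

    ``records_by_condition`` maps condition label → MigrationRecords or plain
    distances. Returns a (condition, n, mean, SD) table ordered by condition
    label, plus per-condition (counts, bin edges) histograms.
    """
    if not records_by_condition:
        raise ValueError("no conditions given")
    rows = []
    hists: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond in sorted(records_by_condition):
        recs = records_by_condition[cond]
        if len(recs) == 0:
            raise ValueError(f"condition {cond!r} has no records")
        d = np.asarray(
            [r.distance_um if isinstance(r, MigrationRecord) else float(r) for r in recs]
        )
        rows.append(
            {
                "condition": cond,
                "n": d.size,
                "mean_um": float(d.mean()),
                "sd_um": float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
            }
        )
        hists[cond] = np.histogram(d, bins=bins)
    return pd.DataFrame(rows), hists
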