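"""Per-ROI fluorescence quantification.

The background of each fluorescence plane is the mean intensity of the pixels
lying between the outlined ROIs, estimated separately for every acquired
plane and subtracted (negative residuals clipped to zero) before any metric is
computed. Two primary metrics follow the field's high-content conventions:
the mean FI of a ROI's above-threshold pixels, and the area fraction — the
percentage of the ROI's pixels carrying above-threshold signal. The pixel CV
(SD/mean of all background-subtracted ROI pixels, no threshold) captures the
spatial heterogeneity of staining; for the mitochondrial-potential dye this is
the TMRM CV, and the TMRM Ratio compares one spheroid's mean FI at two
timepoints. Positivity calls (e.g. Annexin V) use a cutoff of mean + SD of a
control population; a z-stack staining-homogeneity QC checks that per-plane
mean FI varies by no more than a configurable CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .images import FieldImage
from .segment import SpheroidROI

__all__ = [
    "FluorMetrics",
    "TMRMPair",
    "CutoffRule",
    "estimate_background",
    "background_stats",
    "suggest_threshold",
    "measure_roi",
    "tmrm_ratio",
    "make_cutoff",
    "classify_positive",
    "staining_homogeneity",
]


@dataclass
class FluorMetrics:
    """Per-ROI, per-channel fluorescence summary (all post background subtraction)."""

    spheroid_id: int | str
    channel: str
    mean_fi: float          # au, mean of above-threshold ROI pixels (0 if none)
    area_fraction: float    # %, above-threshold pixels / ROI pixels × 100
    pixel_cv: float         # SD/mean over all ROI pixels; NaN if mean is 0
    background_level: float
    positive: bool | None = None


@dataclass
class TMRMPair:
    """One spheroid's mean FI at two timepoints and their ratio."""

    spheroid_id: int | str
    fi_t1: float
    fi_t2: float
    tmrm_ratio: float       # FI(t2)/FI(t1); NaN and flagged when FI(t1) = 0
    valid: bool = True


@dataclass
class CutoffRule:
    """mean ± SD cutoffs built from a control population."""

    mean: float
    sd: float
    upper: float
    lower: float
    n: int


def _outside_mask(image: FieldImage, rois: list[SpheroidROI]) -> np.ndarray:
    outside = np.ones(image.pixels.shape, dtype=bool)
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        outside[r0:r1, c0:c1] &= ~roi.mask
    return outside


def background_stats(image: FieldImage, rois: list[SpheroidROI]) -> tuple[float, float]:
    """Mean and sample SD of all pixels outside every ROI of this plane."""
    outside = _outside_mask(image, rois)
    vals = image.pixels[outside]
    if vals.size == 0:
        raise ValueError("ROIs cover the entire field; no background pixels")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def estimate_background(image: FieldImage, rois: list[SpheroidROI]) -> float:
    """Mean intensity between the outlined ROIs (per-plane background).

    With no ROIs this is the whole-field mean. Estimated independently for
    each acquired plane; never shared across planes.
    """
    return background_stats(image, rois)[0]


def suggest_threshold(image: FieldImage, rois: list[SpheroidROI], k: float = 2.0) -> float:
    """Default positivity threshold: k × background SD (background-subtracted units)."""
    return k * background_stats(image, rois)[1]


def measure_roi(
    image: FieldImage,
    roi: SpheroidROI,
    background: float,
    threshold: float,
) -> FluorMetrics:
    """FI metrics of one ROI on one (background-corrected) plane.

    ``threshold`` is in background-subtracted units and applied after
    subtraction, so adding a constant offset to the whole plane (and hence to
    its background estimate) leaves every metric unchanged.
    """
    vals = roi.pixels(image)
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    sub = np.clip(vals - background, 0.0, None)
    above = sub >= threshold
    mean_fi = float(sub[above].mean()) if above.any() else 0.0
    area_fraction = 100.0 * above.sum() / sub.size
    mean_all = sub.mean()
    if mean_all > 0 and sub.size > 1:
        pixel_cv = float(np.std(sub, ddof=1) / mean_all)
    else:
        pixel_cv = math.nan if mean_all == 0 else 0.0
    return FluorMetrics(
        spheroid_id=roi.chamber if roi.chamber is not None else roi.id,
        channel=image.channel,
        mean_fi=mean_fi,
        area_fraction=float(area_fraction),
        pixel_cv=pixel_cv,
        background_level=background,
    )


def tmrm_ratio(m1: FluorMetrics, m2: FluorMetrics) -> TMRMPair:
    """Ratio of one spheroid's mean FI at two timepoints.

    Undefined (NaN, flagged invalid) when the first-timepoint FI is zero.
    """
    if m1.spheroid_id != m2.spheroid_id:
        raise ValueError("metrics must belong to the same spheroid")
    if m1.mean_fi > 0:
        return TMRMPair(m1.spheroid_id, m1.mean_fi, m2.mean_fi, m2.mean_fi / m1.mean_fi)
    return TMRMPair(m1.spheroid_id, m1.mean_fi, m2.mean_fi, math.nan, valid=False)


def make_cutoff(reference_values) -> CutoffRule:
    """mean ± sample SD (n−1) cutoffs from a control population (n ≥ 2)."""
    vals = np.asarray(list(reference_values), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 reference values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("reference values must be finite")
    mean = float(vals.mean())
    sd = float(np.std(vals, ddof=1))
    return CutoffRule(mean, sd, mean + sd, mean - sd, int(vals.size))


def classify_positive(
    metrics: FluorMetrics, rule: CutoffRule, attribute: str = "mean_fi"
) -> bool:
    """Positive iff the chosen metric strictly exceeds the upper cutoff.

    Sets and returns the ROI's ``positive`` flag; the boundary value itself
    is negative (strict inequality).
    """
    value = getattr(metrics, attribute)
    metrics.positive = bool(value > rule.upper)
    return metrics.positive


def staining_homogeneity(
    plane_means, cv_limit: float = 0.08
) -> tuple[float, bool]:
    """CV of per-focal-plane mean FI along a spheroid's z axis.

    ``plane_means`` may be numbers or FluorMetrics (their mean_fi is used);
    at least 2 planes are required. QC passes when CV ≤ ``cv_limit``
    (default 0.08, matching a reported ≈8% homogeneity bound).
    """
    vals = np.asarray(
        [m.mean_fi if isinstance(m, FluorMetrics) else float(m) for m in plane_means],
        dtype=float,
    )
    if vals.size < 2:
        raise ValueError("need at least 2 focal planes")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero mean FI across planes; CV undefined")
    cv = float(np.std(vals, ddof=1) / mean)
    return cv, cv <= cv_limit
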