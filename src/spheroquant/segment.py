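"""Spheroid detection on bright-field planes, chamber assignment and tracking.

Spheroids are outlined as regions of interest by Sobel edge detection: the
gradient magnitude is thresholded (Otsu), the edge map closed and hole-filled,
and connected components within a plausible area range become ROIs. Each ROI
is assigned to the microchamber containing its centroid, and the same chamber
index links the same spheroid across timepoints — chamber walls keep each
spheroid in place, so no appearance-based matching is needed.

Coordinates use 0-based pixel indices with physical position
(index + 0.5) × microns_per_pixel (pixel-center convention), x along columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import sobel, threshold_otsu

from .images import FieldImage, GridGeometry

__all__ = [
    "SpheroidROI",
    "ROITrack",
    "segment_field",
    "assign_chambers",
    "track_rois",
    "FieldImage",
    "GridGeometry",
]


@dataclass
class SpheroidROI:
    """A segmented spheroid on one plane.

    ``mask`` is the local boolean membership mask within ``bbox``
    (min_row, min_col, max_row, max_col, half-open); physical quantities are
    in µm / µm². ROIs touching the field border are kept but flagged.
    """

    id: int
    field_id: str
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    area_um2: float
    centroid_um: tuple[float, float]     # (X, Y)
    outline_um: np.ndarray               # (n, 2) polygon, (X, Y) in µm
    microns_per_pixel: float
    chamber: tuple[int, int] | None = None
    touches_border: bool = False

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        microns_per_pixel: float = 1.0,
        roi_id: int = 0,
        field_id: str = "field0",
        chamber: tuple[int, int] | None = None,
    ) -> "SpheroidROI":
        """Build an ROI directly from a full-field boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        ys, xs = np.nonzero(mask)
        if len(xs) == 0:
            raise ValueError("empty mask")
        r0, r1 = ys.min(), ys.max() + 1
        c0, c1 = xs.min(), xs.max() + 1
        mpp = microns_per_pixel
        centroid = ((xs.mean() + 0.5) * mpp, (ys.mean() + 0.5) * mpp)
        padded = np.pad(mask[r0:r1, c0:c1], 1)
        contours = measure.find_contours(padded.astype(float), 0.5)
        contour = max(contours, key=len) - 1.0
        outline = np.column_stack(
            [(contour[:, 1] + c0 + 0.5) * mpp, (contour[:, 0] + r0 + 0.5) * mpp]
        )
        return cls(
            id=roi_id,
            field_id=field_id,
            bbox=(int(r0), int(c0), int(r1), int(c1)),
            mask=mask[r0:r1, c0:c1],
            area_um2=float(len(xs)) * mpp**2,
            centroid_um=centroid,
            outline_um=outline,
            microns_per_pixel=mpp,
            chamber=chamber,
        )

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    def pixels(self, image: FieldImage | np.ndarray) -> np.ndarray:
        """Intensity values of this ROI's member pixels on ``image``."""
        arr = image.pixels if isinstance(image, FieldImage) else np.asarray(image)
        r0, c0, r1, c1 = self.bbox
        return arr[r0:r1, c0:c1][self.mask]

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass
class ROITrack:
    """The same spheroid observed at successive timepoints (one chamber)."""

    spheroid_id: str
    chamber: tuple[int, int]
    rois: list[SpheroidROI] = field(default_factory=list)


def segment_field(
    image: FieldImage,
    min_area: float = 500.0,
    max_area: float = 50000.0,
    closing_radius: int = 3,
    edge_compensation_px: int = 1,
) -> list[SpheroidROI]:
    """Detect spheroid ROIs on a bright-field plane.

    Pipeline: Sobel gradient magnitude → Otsu threshold (floored at
    mean + 3 SD of the gradient, so pure-noise planes yield nothing) →
    morphological closing (disk, ``closing_radius`` px) → hole filling →
    erosion by ``edge_compensation_px`` (the gradient of a step edge has
    one-pixel support outside the object, so the filled component is dilated
    by ~1 px) → connected components filtered to [min_area, max_area] µm².

    A blank/constant plane returns an empty list. ``min_area >= max_area``
    is a parameter error.
    """
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    img = image.pixels
    if np.ptp(img) == 0:
        return []
    grad = sobel(img)
    thresh = max(threshold_otsu(grad), float(grad.mean() + 3.0 * grad.std()))
    edges = grad > thresh
    if not edges.any():
        return []
    closed = morphology.closing(edges, morphology.disk(closing_radius))
    filled = ndi.binary_fill_holes(closed)
    if edge_compensation_px > 0:
        filled = morphology.erosion(filled, morphology.disk(edge_compensation_px))
    labels = measure.label(filled)
    mpp = image.microns_per_pixel
    rois: list[SpheroidROI] = []
    rid = 0
    for prop in measure.regionprops(labels):
        area_um2 = prop.area * mpp**2
        if not min_area <= area_um2 <= max_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        mask = prop.image
        cy, cx = prop.centroid
        centroid_um = ((cx + 0.5) * mpp, (cy + 0.5) * mpp)
        padded = np.pad(mask, 1)
        contours = measure.find_contours(padded.astype(float), 0.5)
        contour = max(contours, key=len) - 1.0  # undo padding
        outline = np.column_stack(
            [(contour[:, 1] + c0 + 0.5) * mpp, (contour[:, 0] + r0 + 0.5) * mpp]
        )
        touches = r0 == 0 or c0 == 0 or r1 == img.shape[0] or c1 == img.shape[1]
        rois.append(
            SpheroidROI(
                id=rid,
                field_id=image.field_id,
                bbox=(r0, c0, r1, c1),
                mask=mask,
                area_um2=area_um2,
                centroid_um=centroid_um,
                outline_um=outline,
                microns_per_pixel=mpp,
                touches_border=touches,
            )
        )
        rid += 1
    return rois


def assign_chambers(rois: list[SpheroidROI], grid: GridGeometry) -> list[SpheroidROI]:
    """Assign each ROI to the grid cell containing its centroid (in place).

    Centroids outside the grid extent get ``None``. A centroid exactly on a
    cell boundary is resolved toward the lower (row, col) index.
    """
    for roi in rois:
        x, y = roi.centroid_um
        fx = (x - grid.origin_x_um) / grid.pitch_um
        fy = (y - grid.origin_y_um) / grid.pitch_um
        col = int(np.floor(fx))
        row = int(np.floor(fy))
        if fx == col and col > 0:   # boundary tie → lower index
            col -= 1
        if fy == row and row > 0:
            row -= 1
        if 0 <= row < grid.rows and 0 <= col < grid.cols:
            roi.chamber = (row, col)
        else:
            roi.chamber = None
    return rois


def track_rois(
    rois_t1: list[SpheroidROI],
    rois_t2: list[SpheroidROI],
) -> tuple[list[ROITrack], list[SpheroidROI], list[tuple[int, int]]]:
    """Pair ROIs across two timepoints by identical chamber index.

    Returns (tracks, unpaired ROIs, ambiguous chambers). A chamber holding
    two ROIs at one timepoint is flagged ambiguous and excluded from tracks;
    chamberless ROIs are always unpaired.
    """
    def by_chamber(rois):
        d: dict[tuple[int, int], list[SpheroidROI]] = {}
        for r in rois:
            if r.chamber is not None:
                d.setdefault(r.chamber, []).append(r)
        return d

    d1, d2 = by_chamber(rois_t1), by_chamber(rois_t2)
    ambiguous = sorted(
        {ch for ch, rs in d1.items() if len(rs) > 1}
        | {ch for ch, rs in d2.items() if len(rs) > 1}
    )
    tracks: list[ROITrack] = []
    unpaired: list[SpheroidROI] = [r for r in rois_t1 + rois_t2 if r.chamber is None]
    for ch in sorted(set(d1) | set(d2)):
        if ch in ambiguous:
            continue
        if ch in d1 and ch in d2:
            tracks.append(ROITrack(f"r{ch[0]}c{ch[1]}", ch, [d1[ch][0], d2[ch][0]]))
        else:
            unpaired.extend(d1.get(ch, []) + d2.get(ch, []))
    return tracks, unpaired, ambiguous
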