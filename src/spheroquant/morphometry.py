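"""Shape, texture and cellometry estimates per spheroid ROI.

Sphericity uses the standard moment-based roundness
``S = m00² / (2π (µ20 + µ02))`` — 1 for an ideal disk, ``2ab/(a²+b²)`` for an
ellipse with semi-axes a, b — computed from the binary mask's central moments
in pixel units. Texture (entropy, gray SD, gray range) is computed over the
ROI's raw gray levels. Cellometry converts projected areas to sphere-equivalent
volumes: cells in these non-adherent cultures stay globular, so a projected
cell area yields a cell volume, and a spheroid sectional area divided by the
single-cell volume yields an estimated cell count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShapeMetrics",
    "TextureMetrics",
    "central_moments",
    "sphericity",
    "texture",
    "cell_volume_from_area",
    "cells_per_spheroid",
    "doubling_time",
]


@dataclass
class ShapeMetrics:
    spheroid_id: int | str | None
    area_um2: float
    sphericity: float
    degenerate: bool = False


@dataclass
class TextureMetrics:
    entropy: float       # nats
    gray_sd: float       # au, sample SD (n-1)
    gray_range: float    # au, max - min


def central_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """(m00, µ20, µ02) of a binary mask in pixel units.

    m00 is the pixel count; µ20 and µ02 are the second central moments about
    the mask centroid, with x along columns and y along rows.
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    m00 = float(len(xs))
    if m00 == 0:
        raise ValueError("empty mask")
    xbar = xs.sum() / m00
    ybar = ys.sum() / m00
    mu20 = float(np.sum((xs - xbar) ** 2))
    mu02 = float(np.sum((ys - ybar) ** 2))
    return m00, mu20, mu02


def sphericity(mask: np.ndarray, degenerate_tol: float = 0.05) -> ShapeMetrics:
    """Moment-based roundness of a binary mask.

    S = m00²/(2π(µ20+µ02)); line-like masks give S near 0 and are flagged
    ``degenerate``. Requires at least 5 pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 5:
        raise ValueError("mask must contain at least 5 pixels")
    m00, mu20, mu02 = central_moments(mask)
    s = m00**2 / (2.0 * math.pi * (mu20 + mu02))
    return ShapeMetrics(None, m00, s, degenerate=s < degenerate_tol)


def texture(pixels: np.ndarray, mask: np.ndarray | None = None, bins: int = 64) -> TextureMetrics:
    """Entropy (nats), gray SD and gray range of the ROI's gray levels.

    Entropy is the Shannon entropy of the gray-level histogram over ``bins``
    equal-width bins spanning the ROI's own min–max, so absolute values are
    comparative, not calibrated. A constant ROI has entropy 0, SD 0, range 0.
    """
    pixels = np.asarray(pixels, dtype=float)
    vals = pixels[np.asarray(mask, dtype=bool)] if mask is not None else pixels.ravel()
    if vals.size == 0:
        raise ValueError("no ROI pixels")
    rng = float(vals.max() - vals.min())
    if rng == 0.0:
        return TextureMetrics(0.0, 0.0, 0.0)
    counts, _ = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
    p = counts[counts > 0] / vals.size
    h = float(-np.sum(p * np.log(p)))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return TextureMetrics(h, sd, rng)


def cell_volume_from_area(area_um2: float) -> float:
    """Sphere-equivalent volume (pL) of a globular cell from its projected area.

    r = √(area/π); V = (4/3)πr³; 1 pL = 1000 µm³.
    """
    if area_um2 <= 0:
        raise ValueError("area must be > 0")
    r = math.sqrt(area_um2 / math.pi)
    return (4.0 / 3.0) * math.pi * r**3 / 1000.0


def cells_per_spheroid(sectional_area_um2: float, cell_volume_pl: float) -> int:
    """Estimated cell count from a spheroid's sectional area.

    The spheroid volume is taken sphere-equivalent (r = √(A/π),
    V = (4/3)πr³) and divided by the mean single-cell volume; rounded to the
    nearest integer, never below 1.
    """
    if sectional_area_um2 <= 0 or cell_volume_pl <= 0:
        raise ValueError("inputs must be > 0")
    v_sph_pl = cell_volume_from_area(sectional_area_um2)
    return max(int(round(v_sph_pl / cell_volume_pl)), 1)


def doubling_time(n1: float, n2: float, dt_hours: float) -> float:
    """Population doubling time Td = dt·ln2/ln(N2/N1) in hours.

    Returns NaN (undefined growth) when N2 <= N1.
    """
    if n1 <= 0 or n2 <= 0 or dt_hours <= 0:
        raise ValueError("counts and interval must be > 0")
    if n2 <= n1:
        return math.nan
    return dt_hours * math.log(2.0) / math.log(n2 / n1)
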