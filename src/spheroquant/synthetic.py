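"""Synthetic microchamber-array fields with ground truth.

Real spheroid experiments image a regular grid of hydrogel microchambers, each
holding at most one multicellular spheroid, over several timepoints and
channels. No raw image data accompanies the measurements this package
re-implements, so this module generates fields with the same statistical
structure — day-2 sectional areas of about 4900 ± 2450 µm², growth ratios
drawn from a configurable mixture (control mean ≈ 1.24, with optional planted
high-/low-proliferating components), fluorescence channels with controllable
positive-area fractions, per-spheroid multiplicative intensity factors between
timepoints, and Rayleigh-distributed displacements for the invasion assay —
and records every generated quantity in a truth table so each analysis stage
can be tested against known answers.

Spheroids are rendered as ellipses: a bright background with a dark rim and a
mid-gray (optionally textured) interior on the bright-field analog, and a
foreground-over-background concentric region on fluorescence planes. All
randomness flows from one :class:`numpy.random.Generator` seeded once, with
draws in a fixed documented order, so identical configurations reproduce
identical images and tables bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .images import FieldImage, GridGeometry
from .morphometry import cells_per_spheroid

__all__ = [
    "ChannelSpec",
    "SimConfig",
    "SizingError",
    "simulate_array",
    "simulate_invasion",
    "write_truth",
    "read_truth",
]


class SizingError(ValueError):
    """A sampled spheroid does not fit inside its microchamber."""


@dataclass
class ChannelSpec:
    """Generative description of one fluorescence channel.

    ``frac_mean``/``frac_sd`` set the per-spheroid true positive-area fraction
    (clipped to [0, 1]); ``foreground`` is the mean above-background signal of
    positive pixels and ``intensity_sd`` its per-spheroid spread (a graded
    whole-spheroid channel is ``frac_mean=1`` with ``intensity_sd > 0``);
    ``ratio_mean``/``ratio_sd``, if set, multiply each spheroid's intensity
    between the two timepoints (TMRM-like two-timepoint structure).
    """

    label: str
    frac_mean: float = 1.0
    frac_sd: float = 0.0
    foreground: float = 2000.0
    background: float = 100.0
    noise_sd: float = 20.0
    intensity_sd: float = 0.0
    ratio_mean: float | None = None
    ratio_sd: float = 0.0


@dataclass
class SimConfig:
    """Everything the generator needs; defaults state the emulated experiment.

    Areas are day-2 sectional areas in µm² (4900 ± 2450 by default); the
    growth-ratio mixture defaults to the single control component
    (mean 1.24, SD 0.20); ``displacement_scale`` is the Rayleigh σ of
    per-spheroid displacements in invasion mode.
    """

    grid_rows: int = 4
    grid_cols: int = 4
    chamber_pitch: float = 160.0           # µm
    microns_per_pixel: float = 1.0
    occupancy: float = 1.0
    area_mean: float = 4900.0              # µm², day-2 sectional area
    area_sd: float = 2450.0
    min_area: float = 200.0                # rejection floor, µm²
    gr_components: list[tuple[float, float, float]] = dc_field(
        default_factory=lambda: [(1.0, 1.24, 0.20)]
    )  # (weight, GR mean, GR sd)
    timepoints: tuple[float, float] = (48.0, 72.0)  # hours
    channel_specs: list[ChannelSpec] = dc_field(default_factory=list)
    axis_ratio_mean: float = 1.0           # minor/major; 1 = round phenotype
    axis_ratio_sd: float = 0.0
    center_jitter: float = 0.05            # fraction of pitch, per axis
    displacement_scale: float = 0.0        # Rayleigh σ, µm (invasion mode)
    cell_volume_pl: float = 1.69           # single-cell volume for truth counts
    rng_seed: int = 0
    # bright-field rendering
    bf_background: float = 1000.0
    bf_interior: float = 600.0
    bf_rim: float = 200.0
    bf_noise_sd: float = 30.0
    bf_texture_sd: float = 0.0             # interior granularity ("rough" phenotype)
    rim_width_um: float | None = None      # default 3 px

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.area_mean <= 0 or self.microns_per_pixel <= 0:
            raise ValueError("area_mean and microns_per_pixel must be > 0")
        w = np.array([c[0] for c in self.gr_components], dtype=float)
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("GR component weights must be >= 0 and sum to 1")

    @property
    def grid(self) -> GridGeometry:
        return GridGeometry(self.grid_rows, self.grid_cols, self.chamber_pitch)

    @property
    def field_shape_px(self) -> tuple[int, int]:
        mpp = self.microns_per_pixel
        return (
            int(math.ceil(self.grid_rows * self.chamber_pitch / mpp)),
            int(math.ceil(self.grid_cols * self.chamber_pitch / mpp)),
        )


@dataclass
class _Spheroid:
    """Internal per-spheroid sample; flattened into the truth table."""

    sid: int
    row: int
    col: int
    center: tuple[float, float]            # µm, timepoint 1
    area1: float
    gr: float
    axis_ratio: float
    angle: float
    chan_fracs: dict
    chan_intens: dict
    chan_ratios: dict
    dx: float = 0.0
    dy: float = 0.0
    clipped: bool = False

    def axes_at(self, area: float, axis_ratio: float | None = None) -> tuple[float, float]:
        q = self.axis_ratio if axis_ratio is None else axis_ratio
        a = math.sqrt(area / (math.pi * q))
        return a, q * a


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """Rejection-sample a normal conditioned on exceeding ``low``."""
    if sd == 0:
        if mean <= low:
            raise ValueError("degenerate distribution entirely below floor")
        return mean
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise RuntimeError("truncated-normal rejection sampling failed")


def _sample_spheroids(config: SimConfig, rng: np.random.Generator) -> list[_Spheroid]:
    """Draw per-chamber occupancy and per-spheroid parameters, row-major.

    Draw order per occupied chamber: area, GR component + value, axis ratio,
    orientation, center jitter, then per channel (fraction, intensity, ratio).
    """
    pitch = config.chamber_pitch
    weights = np.array([c[0] for c in config.gr_components])
    cum_w = np.cumsum(weights)
    spheroids: list[_Spheroid] = []
    sid = 0
    for i in range(config.grid_rows):
        for j in range(config.grid_cols):
            if rng.random() >= config.occupancy:
                continue
            area1 = _truncated_normal(rng, config.area_mean, config.area_sd, config.min_area)
            comp = int(np.searchsorted(cum_w, rng.random(), side="right"))
            comp = min(comp, len(config.gr_components) - 1)
            _, gmean, gsd = config.gr_components[comp]
            gr = _truncated_normal(rng, gmean, gsd, 0.05)
            q = 1.0
            angle = 0.0
            if config.axis_ratio_sd > 0 or config.axis_ratio_mean < 1.0:
                q = float(np.clip(rng.normal(config.axis_ratio_mean, config.axis_ratio_sd), 0.3, 1.0))
                angle = rng.uniform(0.0, math.pi)
            jx, jy = rng.uniform(-1.0, 1.0, 2) * config.center_jitter * pitch
            cx = (j + 0.5) * pitch + jx
            cy = (i + 0.5) * pitch + jy
            # largest extent over both timepoints must fit inside the chamber
            a_max = math.sqrt(area1 * max(gr, 1.0) / (math.pi * q))
            if a_max + max(abs(jx), abs(jy)) >= pitch / 2.0:
                raise SizingError(
                    f"chamber pitch {pitch} µm too small for sampled spheroid "
                    f"(semi-major axis {a_max:.1f} µm); increase chamber_pitch "
                    "or reduce area_mean/area_sd"
                )
            fracs, intens, ratios = {}, {}, {}
            for ch in config.channel_specs:
                fracs[ch.label] = float(np.clip(rng.normal(ch.frac_mean, ch.frac_sd), 0.0, 1.0))
                intens[ch.label] = max(float(rng.normal(ch.foreground, ch.intensity_sd)), 0.0)
                if ch.ratio_mean is not None:
                    ratios[ch.label] = _truncated_normal(rng, ch.ratio_mean, ch.ratio_sd, 0.05)
                else:
                    ratios[ch.label] = 1.0
            spheroids.append(
                _Spheroid(sid, i, j, (cx, cy), area1, gr, q, angle, fracs, intens, ratios)
            )
            sid += 1
    return spheroids


def _norm_radius(
    shape_px: tuple[int, int],
    center_um: tuple[float, float],
    a: float,
    b: float,
    angle: float,
    mpp: float,
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Normalized elliptical radius ρ over the shape's bounding box.

    ρ <= 1 is the ellipse interior. Pixel centers are at (index + 0.5) * mpp.
    """
    cx, cy = center_um
    ext = max(a, b) + 2 * mpp
    r0 = max(int((cy - ext) / mpp) - 1, 0)
    r1 = min(int((cy + ext) / mpp) + 2, shape_px[0])
    c0 = max(int((cx - ext) / mpp) - 1, 0)
    c1 = min(int((cx + ext) / mpp) + 2, shape_px[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    x = (cc + 0.5) * mpp - cx
    y = (rr + 0.5) * mpp - cy
    u = x * math.cos(angle) + y * math.sin(angle)
    v = -x * math.sin(angle) + y * math.cos(angle)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    return (slice(r0, r1), slice(c0, c1)), rho


def _render_brightfield(
    config: SimConfig,
    spheroids: list[_Spheroid],
    geoms: list[tuple[tuple[float, float], float, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    mpp = config.microns_per_pixel
    shape = config.field_shape_px
    img = np.full(shape, config.bf_background, dtype=float)
    rim_w = config.rim_width_um if config.rim_width_um is not None else 3.0 * mpp
    for center, a, b, angle in geoms:
        sl, rho = _norm_radius(shape, center, a, b, angle, mpp)
        interior = rho <= 1.0
        patch = img[sl]
        vals = np.full(rho.shape, config.bf_interior)
        if config.bf_texture_sd > 0:
            vals += rng.normal(0.0, config.bf_texture_sd, rho.shape)
        rim_frac = rim_w / math.sqrt(a * b)
        rim = interior & (rho >= 1.0 - rim_frac)
        patch[interior] = vals[interior]
        patch[rim] = config.bf_rim
    if config.bf_noise_sd > 0:
        img += rng.normal(0.0, config.bf_noise_sd, shape)
    return np.clip(img, 0.0, None)


def _render_channel(
    config: SimConfig,
    ch: ChannelSpec,
    entries: list[tuple[tuple[float, float], float, float, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """entries: (center, a, b, angle, positive fraction, above-background intensity)."""
    mpp = config.microns_per_pixel
    shape = config.field_shape_px
    img = np.full(shape, ch.background, dtype=float)
    for center, a, b, angle, frac, inten in entries:
        if frac <= 0.0:
            continue
        sl, rho = _norm_radius(shape, center, a, b, angle, mpp)
        pos = rho <= math.sqrt(frac)  # concentric sub-ellipse of area frac·πab
        img[sl][pos] = ch.background + inten
    if ch.noise_sd > 0:
        img += rng.normal(0.0, ch.noise_sd, shape)
    return np.clip(img, 0.0, None)


def _truth_frame(config: SimConfig, spheroids: list[_Spheroid], invasion: bool) -> pd.DataFrame:
    rows = []
    t1, t2 = config.timepoints if not invasion else (0.0, 18.0)
    for s in spheroids:
        area2 = s.area1 * s.gr if not invasion else s.area1
        for tp, area, (cx, cy) in (
            (t1, s.area1, s.center),
            (t2, area2, (s.center[0] + s.dx, s.center[1] + s.dy)),
        ):
            a, b = s.axes_at(area)
            rec = {
                "spheroid_id": s.sid,
                "chamber_row": s.row,
                "chamber_col": s.col,
                "timepoint": tp,
                "center_x_um": cx,
                "center_y_um": cy,
                "semi_major_um": a,
                "semi_minor_um": b,
                "angle_rad": s.angle,
                "area_um2": area,
                "gr": s.gr,
                "cell_count": cells_per_spheroid(area, config.cell_volume_pl),
                "dx_um": s.dx,
                "dy_um": s.dy,
                "clipped": s.clipped,
            }
            for ch in config.channel_specs:
                factor = s.chan_ratios[ch.label] if tp == t2 else 1.0
                rec[f"{ch.label}_frac"] = s.chan_fracs[ch.label]
                rec[f"{ch.label}_intensity"] = s.chan_intens[ch.label] * factor
            rows.append(rec)
    cols = [
        "spheroid_id", "chamber_row", "chamber_col", "timepoint",
        "center_x_um", "center_y_um", "semi_major_um", "semi_minor_um",
        "angle_rad", "area_um2", "gr", "cell_count", "dx_um", "dy_um", "clipped",
    ] + [f"{ch.label}_{k}" for ch in config.channel_specs for k in ("frac", "intensity")]
    return pd.DataFrame(rows, columns=cols)


def simulate_array(config: SimConfig) -> tuple[list[FieldImage], pd.DataFrame]:
    """Generate a two-timepoint microchamber-array acquisition with truth.

    Returns one bright-field plane per timepoint, one plane per fluorescence
    channel per timepoint, and the truth table (one row per spheroid per
    timepoint). Raises :class:`SizingError` if any sampled spheroid cannot fit
    inside its chamber.
    """
    rng = np.random.default_rng(config.rng_seed)
    spheroids = _sample_spheroids(config, rng)
    t1, t2 = config.timepoints
    fields: list[FieldImage] = []
    for tp in (t1, t2):
        geoms = []
        for s in spheroids:
            area = s.area1 if tp == t1 else s.area1 * s.gr
            a, b = s.axes_at(area)
            geoms.append((s.center, a, b, s.angle))
        img = _render_brightfield(config, spheroids, geoms, rng)
        fields.append(FieldImage(img, "brightfield", tp, config.microns_per_pixel))
    for ch in config.channel_specs:
        for tp in (t1, t2):
            entries = []
            for s in spheroids:
                area = s.area1 if tp == t1 else s.area1 * s.gr
                a, b = s.axes_at(area)
                factor = s.chan_ratios[ch.label] if tp == t2 else 1.0
                entries.append(
                    (s.center, a, b, s.angle, s.chan_fracs[ch.label], s.chan_intens[ch.label] * factor)
                )
            img = _render_channel(config, ch, entries, rng)
            fields.append(FieldImage(img, ch.label, tp, config.microns_per_pixel))
    return fields, _truth_frame(config, spheroids, invasion=False)


def simulate_invasion(
    config: SimConfig,
    displacements: list[tuple[float, float]] | None = None,
    flatten: float = 1.0,
) -> tuple[list[FieldImage], pd.DataFrame]:
    """Generate a two-timepoint matrix-invasion field pair with truth.

    Each spheroid keeps its sectional area but translates by a displacement
    drawn from a Rayleigh distribution with σ = ``displacement_scale`` (µm) at
    a uniform angle, and is optionally flattened (axis ratio multiplied by
    ``flatten`` < 1). ``displacements`` overrides the sampling with explicit
    (dx, dy) pairs, one per spheroid. Displacements that would push a spheroid
    outside the field are clipped and flagged in the truth table.
    """
    if config.displacement_scale is None:
        raise ValueError("displacement_scale must be set for invasion mode")
    rng = np.random.default_rng(config.rng_seed)
    spheroids = _sample_spheroids(config, rng)
    h_um = config.field_shape_px[0] * config.microns_per_pixel
    w_um = config.field_shape_px[1] * config.microns_per_pixel
    for idx, s in enumerate(spheroids):
        if displacements is not None:
            dx, dy = displacements[idx]
        elif config.displacement_scale > 0:
            d = rng.rayleigh(config.displacement_scale)
            phi = rng.uniform(0.0, 2.0 * math.pi)
            dx, dy = d * math.cos(phi), d * math.sin(phi)
        else:
            dx, dy = 0.0, 0.0
        a2, _ = s.axes_at(s.area1, s.axis_ratio * flatten)
        cx2 = s.center[0] + dx
        cy2 = s.center[1] + dy
        cx2c = float(np.clip(cx2, a2 + 1.0, w_um - a2 - 1.0))
        cy2c = float(np.clip(cy2, a2 + 1.0, h_um - a2 - 1.0))
        s.clipped = (cx2c != cx2) or (cy2c != cy2)
        s.dx = cx2c - s.center[0]
        s.dy = cy2c - s.center[1]
    fields = []
    for tp in (0.0, 18.0):
        geoms = []
        for s in spheroids:
            q = s.axis_ratio if tp == 0.0 else s.axis_ratio * flatten
            a, b = s.axes_at(s.area1, q)
            center = s.center if tp == 0.0 else (s.center[0] + s.dx, s.center[1] + s.dy)
            geoms.append((center, a, b, s.angle))
        img = _render_brightfield(config, spheroids, geoms, rng)
        fields.append(FieldImage(img, "brightfield", tp, config.microns_per_pixel))
    return fields, _truth_frame(config, spheroids, invasion=True)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the truth table to CSV (one row per spheroid per timepoint)."""
    truth.to_csv(path, index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth CSV written by :func:`write_truth`."""
    return pd.read_csv(path)
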