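"""Field images and their on-disk form.

A :class:`FieldImage` is one 2D intensity plane of a microscopy view field —
one channel at one timepoint — together with the physical pixel size. Stacks
of planes are stored as multi-page TIFF (one page per channel/timepoint, the
per-page description carrying the channel label and timepoint) with a sidecar
JSON holding the pixel size and, for microchamber arrays, the grid geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FieldImage", "GridGeometry", "save_field_stack", "load_field_stack"]


@dataclass
class FieldImage:
    """One acquired intensity plane.

    Parameters
    ----------
    pixels : 2D float array, arbitrary intensity units, non-negative.
    channel : channel label, e.g. ``"brightfield"`` or ``"annexin"``.
    timepoint : acquisition time in hours.
    microns_per_pixel : physical pixel size (µm/px), > 0.
    field_id : identifier of the view field.
    """

    pixels: np.ndarray
    channel: str
    timepoint: float
    microns_per_pixel: float
    field_id: str = "field0"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D plane")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class GridGeometry:
    """Microchamber grid layout in physical coordinates.

    The origin is the top-left corner of the grid in µm, measured from the
    field's top-left pixel *center* (pixel-center convention: physical
    coordinate = (index + 0.5) * microns_per_pixel).
    """

    rows: int
    cols: int
    pitch_um: float
    origin_x_um: float = 0.0
    origin_y_um: float = 0.0

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "pitch_um": self.pitch_um,
            "origin_x_um": self.origin_x_um,
            "origin_y_um": self.origin_y_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(**d)


def save_field_stack(
    fields: list[FieldImage],
    path: str | Path,
    grid: GridGeometry | None = None,
) -> None:
    """Write planes as a multi-page 16-bit TIFF plus a ``.json`` sidecar.

    Intensities are clipped to [0, 65535] and rounded; the sidecar records
    microns_per_pixel, field id, per-page (channel, timepoint) and the grid.
    """
    if not fields:
        raise ValueError("nothing to write")
    path = Path(path)
    mpp = fields[0].microns_per_pixel
    pages = []
    with tifffile.TiffWriter(path) as tif:
        for f in fields:
            data = np.clip(np.round(f.pixels), 0, 65535).astype(np.uint16)
            desc = json.dumps({"channel": f.channel, "timepoint": f.timepoint})
            tif.write(data, description=desc)
            pages.append({"channel": f.channel, "timepoint": f.timepoint})
    sidecar = {
        "microns_per_pixel": mpp,
        "field_id": fields[0].field_id,
        "pages": pages,
        "grid": grid.to_dict() if grid is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_field_stack(path: str | Path) -> tuple[list[FieldImage], GridGeometry | None]:
    """Read a stack written by :func:`save_field_stack`."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mpp = sidecar["microns_per_pixel"]
    fields = []
    with tifffile.TiffFile(path) as tif:
        for page, meta in zip(tif.pages, sidecar["pages"]):
            fields.append(
                FieldImage(
                    pixels=page.asarray().astype(float),
                    channel=meta["channel"],
                    timepoint=meta["timepoint"],
                    microns_per_pixel=mpp,
                    field_id=sidecar["field_id"],
                )
            )
    grid = GridGeometry.from_dict(sidecar["grid"]) if sidecar["grid"] else None
    return fields, grid
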