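import numpy as np
import pytest

import spheroquant as sq


def disk_mask(radius_px: int, pad: int = 5, shape=None, center=None) -> np.ndarray:
    """Rasterized disk: pixels whose centers lie within radius of the center."""
    if shape is None:
        n = 2 * (radius_px + pad) + 1
        shape = (n, n)
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr + 0.5 - center[0]) ** 2 + (cc + 0.5 - center[1]) ** 2 <= radius_px**2


def ellipse_mask(a_px: float, b_px: float, pad: int = 5, angle: float = 0.0) -> np.ndarray:
    n = 2 * int(max(a_px, b_px) + pad) + 1
    c = n / 2
    rr, cc = np.mgrid[:n, :n]
    x = cc + 0.5 - c
    y = rr + 0.5 - c
    u = x * np.cos(angle) + y * np.sin(angle)
    v = -x * np.sin(angle) + y * np.cos(angle)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_sim():
    """3x3 fully occupied array with one area-fraction channel; seeded."""
    cfg = sq.SimConfig(
        grid_rows=3,
        grid_cols=3,
        rng_seed=11,
        min_area=800.0,
        channel_specs=[
            sq.ChannelSpec("annexin", frac_mean=0.558, frac_sd=0.0, foreground=2000.0,
                           background=100.0, noise_sd=20.0)
        ],
    )
    fields, truth = sq.simulate_array(cfg)
    return cfg, fields, truth


def truth_row(truth, chamber, timepoint):
    sel = truth[
        (truth.chamber_row == chamber[0])
        & (truth.chamber_col == chamber[1])
        & (truth.timepoint == timepoint)
    ]
    assert len(sel) == 1
    return sel.iloc[0]
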