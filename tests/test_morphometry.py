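"""Shape/texture metrics and cellometry against closed forms and oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheroquant as sq
from spheroquant.morphometry import central_moments

from conftest import disk_mask, ellipse_mask


def brute_force_moments(mask):
    """Independent oracle: direct pixel summation with fsum accumulation."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    m00 = float(len(xs))
    xbar = math.fsum(float(x) for x in xs) / m00
    ybar = math.fsum(float(y) for y in ys) / m00
    mu20 = math.fsum((float(x) - xbar) ** 2 for x in xs)
    mu02 = math.fsum((float(y) - ybar) ** 2 for y in ys)
    return m00, mu20, mu02


class TestSphericity:
    def test_disk_is_one(self):
        s = sq.sphericity(disk_mask(50))
        assert s.sphericity == pytest.approx(1.0, abs=0.02)
        assert not s.degenerate

    @pytest.mark.parametrize("a,b", [(60, 30), (40, 32), (50, 20)])
    def test_ellipse_closed_form(self, a, b):
        expected = 2 * a * b / (a**2 + b**2)
        s = sq.sphericity(ellipse_mask(a, b))
        assert s.sphericity == pytest.approx(expected, abs=0.02)

    def test_translation_and_rotation_invariance(self):
        base = ellipse_mask(40, 24)
        s0 = sq.sphericity(base).sphericity
        shifted = np.zeros((200, 200), dtype=bool)
        shifted[60 : 60 + base.shape[0], 35 : 35 + base.shape[1]] = base
        assert sq.sphericity(shifted).sphericity == pytest.approx(s0, rel=1e-12)
        assert sq.sphericity(np.rot90(base)).sphericity == pytest.approx(s0, rel=1e-12)

    def test_strictly_decreasing_in_axis_ratio(self):
        vals = [sq.sphericity(ellipse_mask(40, 40 * q)).sphericity
                for q in (1.0, 0.8, 0.6, 0.4)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_degenerate_line_flagged(self):
        mask = np.zeros((3, 200), dtype=bool)
        mask[1, :] = True
        s = sq.sphericity(mask)
        assert s.degenerate and s.sphericity < 0.05

    def test_too_small(self):
        with pytest.raises(ValueError):
            sq.sphericity(np.eye(2, dtype=bool))

    def test_brute_force_oracle(self):
        """Implementation moments match direct pixel summation on <=50x50 masks."""
        rng = np.random.default_rng(5)
        masks = [disk_mask(12), ellipse_mask(20, 9, angle=0.7),
                 rng.random((50, 50)) > 0.5]
        for mask in masks:
            m00, mu20, mu02 = central_moments(mask)
            o00, o20, o02 = brute_force_moments(mask)
            assert m00 == o00  # integer-exact
            assert mu20 == pytest.approx(o20, rel=1e-12)
            assert mu02 == pytest.approx(o02, rel=1e-12)

    def test_rough_phenotype_population_mean(self):
        """Ellipse population with axis ratios tuned to mean sphericity ~0.62."""
        # 2q/(1+q^2) = 0.62  =>  q ~ 0.347
        cfg = sq.SimConfig(grid_rows=5, grid_cols=5, chamber_pitch=280.0, rng_seed=17,
                           min_area=800.0, axis_ratio_mean=0.347, axis_ratio_sd=0.02)
        fields, truth = sq.simulate_array(cfg)
        rois = sq.segment_field(fields[0], min_area=400.0)
        svals = np.array([sq.sphericity(r.mask).sphericity for r in rois])
        per = truth[truth.timepoint == cfg.timepoints[0]]
        q = (per.semi_minor_um / per.semi_major_um).to_numpy()
        s_true = 2 * q / (1 + q**2)
        se = s_true.std(ddof=1) / math.sqrt(len(svals)) + 0.01  # + rasterization
        assert abs(svals.mean() - s_true.mean()) < 3 * se
        assert abs(svals.mean() - 0.62) < 0.05


class TestTexture:
    def test_constant_roi(self):
        t = sq.texture(np.full((20, 20), 9.0))
        assert (t.entropy, t.gray_sd, t.gray_range) == (0.0, 0.0, 0.0)

    def test_two_level_closed_form(self):
        vals = np.zeros((50, 50))
        vals[:25] = 100.0
        t = sq.texture(vals, bins=2)
        assert t.entropy == pytest.approx(math.log(2))
        assert t.gray_sd == pytest.approx(50.0, rel=1e-3)
        assert t.gray_range == pytest.approx(100.0)

    def test_entropy_bounded_by_log_bins(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (64, 64))
        for bins in (2, 16, 64):
            assert 0 <= sq.texture(vals, bins=bins).entropy <= math.log(bins) + 1e-12

    def test_rough_vs_smooth_ordering(self):
        """Textured interiors score higher entropy, SD and range than smooth."""
        out = {}
        for label, tex in (("smooth", 0.0), ("rough", 80.0)):
            cfg = sq.SimConfig(grid_rows=3, grid_cols=3, rng_seed=13, min_area=800.0,
                               bf_texture_sd=tex)
            fields, _ = sq.simulate_array(cfg)
            rois = sq.segment_field(fields[0], min_area=400.0)
            ms = [sq.texture(r.pixels(fields[0])) for r in rois]
            out[label] = (np.mean([m.entropy for m in ms]),
                          np.mean([m.gray_sd for m in ms]),
                          np.mean([m.gray_range for m in ms]))
        assert all(r > s for r, s in zip(out["rough"], out["smooth"]))


class TestCellometry:
    def test_unit_radius_cell(self):
        assert sq.cell_volume_from_area(math.pi) == pytest.approx(4 * math.pi / 3 / 1000)

    def test_printed_mean_volume_inverts(self):
        area = math.pi * 7.4**2
        assert sq.cell_volume_from_area(area) == pytest.approx(1.70, abs=0.01)

    def test_radius_doubling_scales_volume_eightfold(self):
        v1 = sq.cell_volume_from_area(50.0)
        v2 = sq.cell_volume_from_area(200.0)  # doubles r
        assert v2 == pytest.approx(8 * v1)

    def test_printed_cell_counts(self):
        assert sq.cells_per_spheroid(4900.0, 1.69) == pytest.approx(154, rel=0.025)
        assert sq.cells_per_spheroid(4880.0, 2.79) == pytest.approx(94, rel=0.025)

    def test_single_cell(self):
        v = sq.cell_volume_from_area(100.0)
        assert sq.cells_per_spheroid(100.0, v) == 1

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(500, 20000), st.floats(1.05, 3.0))
    def test_monotonicity(self, area, factor):
        n = sq.cells_per_spheroid(area, 1.69)
        assert sq.cells_per_spheroid(area * factor, 1.69) >= n
        assert sq.cells_per_spheroid(area, 1.69 * factor) <= n

    def test_invalid_inputs(self):
        for args in [(-1.0,), (0.0,)]:
            with pytest.raises(ValueError):
                sq.cell_volume_from_area(*args)
        with pytest.raises(ValueError):
            sq.cells_per_spheroid(100.0, 0.0)


class TestDoublingTime:
    def test_hp_twofold_in_24h(self):
        assert sq.doubling_time(116, 232, 24.0) == pytest.approx(24.0)

    def test_half_doubling(self):
        assert sq.doubling_time(100, 100 * math.sqrt(2), 24.0) == pytest.approx(48.0)

    def test_scale_invariance(self):
        td = sq.doubling_time(80, 130, 24.0)
        assert sq.doubling_time(800, 1300, 24.0) == pytest.approx(td)

    def test_no_growth_is_nan(self):
        assert math.isnan(sq.doubling_time(100, 90, 24.0))
        assert math.isnan(sq.doubling_time(100, 100, 24.0))

    def test_invalid(self):
        with pytest.raises(ValueError):
            sq.doubling_time(0, 10, 24.0)
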