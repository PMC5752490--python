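"""Fluorescence metrics: background, thresholded FI, ratios, cutoffs, QC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spheroquant as sq
from spheroquant.quantify import background_stats

from conftest import disk_mask


def _field(arr, channel="fluor", mpp=1.0):
    return sq.FieldImage(np.asarray(arr, dtype=float), channel, 0.0, mpp)


def _disk_roi(radius=10, shape=(64, 64), center=(32, 32)):
    return sq.SpheroidROI.from_mask(disk_mask(radius, shape=shape, center=center))


class TestBackground:
    def test_no_rois_whole_field_mean(self):
        img = _field(np.arange(100.0).reshape(10, 10))
        assert sq.estimate_background(img, []) == pytest.approx(49.5)

    def test_constant_field_with_roi(self):
        img = _field(np.full((64, 64), 3.25))
        assert sq.estimate_background(img, [_disk_roi()]) == pytest.approx(3.25)

    def test_full_cover_error(self):
        img = _field(np.ones((8, 8)))
        roi = sq.SpheroidROI.from_mask(np.ones((8, 8), dtype=bool))
        with pytest.raises(ValueError):
            sq.estimate_background(img, [roi])

    def test_clt_bound_on_noise(self):
        rng = np.random.default_rng(4)
        b, s = 120.0, 15.0
        img = _field(np.clip(rng.normal(b, s, (128, 128)), 0, None))
        roi = _disk_roi(20, shape=(128, 128), center=(64, 64))
        n_out = 128 * 128 - roi.pixel_count
        assert n_out >= 10_000
        est = sq.estimate_background(img, [roi])
        assert abs(est - b) < 3 * s / math.sqrt(n_out)


class TestMeasureROI:
    def test_uniform_above_threshold(self):
        arr = np.zeros((64, 64))
        roi = _disk_roi()
        arr[roi.full_mask(arr.shape)] = 42.0
        m = sq.measure_roi(_field(arr), roi, background=0.0, threshold=10.0)
        assert m.mean_fi == pytest.approx(42.0)
        assert m.area_fraction == pytest.approx(100.0)
        assert m.pixel_cv == pytest.approx(0.0)

    def test_all_below_threshold(self):
        m = sq.measure_roi(_field(np.full((64, 64), 5.0)), _disk_roi(),
                           background=5.0, threshold=10.0)
        assert m.mean_fi == 0.0 and m.area_fraction == 0.0

    def test_empty_mask_error(self):
        roi = _disk_roi()
        roi.mask = np.zeros_like(roi.mask)
        with pytest.raises(ValueError):
            sq.measure_roi(_field(np.ones((64, 64))), roi, 0.0, 0.0)

    def test_offset_invariance(self):
        """Adding a constant to the plane leaves metrics unchanged."""
        rng = np.random.default_rng(1)
        arr = rng.uniform(0, 100, (64, 64))
        roi = _disk_roi()
        for off in (0.0, 57.3):
            img = _field(arr + off)
            bg = sq.estimate_background(img, [roi])
            m = sq.measure_roi(img, roi, bg, threshold=20.0)
            if off == 0.0:
                base = m
        assert m.mean_fi == pytest.approx(base.mean_fi)
        assert m.area_fraction == pytest.approx(base.area_fraction)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 100), min_size=2, max_size=6, unique=True))
    def test_area_fraction_monotone_in_threshold(self, thresholds):
        rng = np.random.default_rng(7)
        arr = rng.uniform(0, 100, (64, 64))
        roi = _disk_roi()
        img = _field(arr)
        fracs = [sq.measure_roi(img, roi, 0.0, t).area_fraction
                 for t in sorted(thresholds)]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_planted_area_fraction_recovery(self, small_sim):
        """True positive fraction 0.558 recovered within 2 points of 55.8%."""
        cfg, fields, truth = small_sim
        bf = fields[0]
        ann = next(f for f in fields if f.channel == "annexin"
                   and f.timepoint == cfg.timepoints[0])
        rois = sq.assign_chambers(sq.segment_field(bf, min_area=400.0), cfg.grid)
        bg, bg_sd = background_stats(ann, rois)
        thr = 2.0 * bg_sd
        for roi in rois:
            m = sq.measure_roi(ann, roi, bg, thr)
            assert abs(m.area_fraction - 55.8) < 2.0


class TestTMRM:
    def _metrics(self, sid, fi):
        return sq.FluorMetrics(sid, "tmrm", fi, 100.0, 0.1, 0.0)

    def test_identity_and_doubling(self):
        assert sq.tmrm_ratio(self._metrics(1, 5.0), self._metrics(1, 5.0)).tmrm_ratio == 1.0
        assert sq.tmrm_ratio(self._metrics(1, 5.0), self._metrics(1, 10.0)).tmrm_ratio == 2.0

    def test_zero_t1_flagged(self):
        pair = sq.tmrm_ratio(self._metrics(1, 0.0), self._metrics(1, 3.0))
        assert not pair.valid and math.isnan(pair.tmrm_ratio)

    def test_mismatched_ids(self):
        with pytest.raises(ValueError):
            sq.tmrm_ratio(self._metrics(1, 1.0), self._metrics(2, 1.0))

    def test_planted_multiplicative_factor_recovery(self):
        """Measured population mean ratio within 3 SE of the planted 1.72."""
        cfg = sq.SimConfig(
            grid_rows=7, grid_cols=6, rng_seed=21, min_area=800.0,
            channel_specs=[sq.ChannelSpec("tmrm", frac_mean=1.0, foreground=3000.0,
                                          noise_sd=20.0, ratio_mean=1.72, ratio_sd=0.61)],
        )
        fields, truth = sq.simulate_array(cfg)
        t1, t2 = cfg.timepoints
        bf = {f.timepoint: f for f in fields if f.channel == "brightfield"}
        tm = {f.timepoint: f for f in fields if f.channel == "tmrm"}
        r1 = sq.assign_chambers(sq.segment_field(bf[t1], min_area=400.0), cfg.grid)
        r2 = sq.assign_chambers(sq.segment_field(bf[t2], min_area=400.0), cfg.grid)
        tracks, _, _ = sq.track_rois(r1, r2)
        # per-plane background over all outlined ROIs, as acquired
        bg1, sd1 = background_stats(tm[t1], r1)
        bg2, sd2 = background_stats(tm[t2], r2)
        ratios = []
        for tr in tracks:
            ms = []
            for roi, plane, bg, sd in ((tr.rois[0], tm[t1], bg1, sd1),
                                       (tr.rois[1], tm[t2], bg2, sd2)):
                m = sq.measure_roi(plane, roi, bg, 2.0 * sd)
                m.spheroid_id = tr.spheroid_id
                ms.append(m)
            pair = sq.tmrm_ratio(*ms)
            assert pair.valid
            ratios.append(pair.tmrm_ratio)
        ratios = np.asarray(ratios)
        assert abs(ratios.mean() - 1.72) < 3 * 0.61 / math.sqrt(ratios.size)
        # per-spheroid measured ratio tracks the planted factor
        per1 = truth[truth.timepoint == t1].set_index(["chamber_row", "chamber_col"])
        per2 = truth[truth.timepoint == t2].set_index(["chamber_row", "chamber_col"])
        for tr, r in zip(tracks, ratios):
            planted = (per2.loc[tr.chamber, "tmrm_intensity"]
                       / per1.loc[tr.chamber, "tmrm_intensity"])
            assert r == pytest.approx(planted, rel=0.05)


class TestCutoff:
    def test_degenerate(self):
        rule = sq.make_cutoff([1.0, 1.0, 1.0])
        assert (rule.mean, rule.sd, rule.upper, rule.lower) == (1.0, 0.0, 1.0, 1.0)

    def test_two_values_closed_form(self):
        rule = sq.make_cutoff([0.0, 2.0])
        assert rule.sd == pytest.approx(math.sqrt(2))
        assert rule.upper == pytest.approx(1 + math.sqrt(2))
        assert rule.lower == pytest.approx(1 - math.sqrt(2))

    def test_too_few(self):
        with pytest.raises(ValueError):
            sq.make_cutoff([1.0])

    def test_control_sample_reproduces_printed_cutoffs(self):
        """N(1.23, 0.20), n=400 control gives cutoffs near 1.43 / 1.03."""
        rng = np.random.default_rng(12)
        rule = sq.make_cutoff(rng.normal(1.23, 0.20, 400))
        se = math.sqrt(0.20**2 / 400 + 0.20**2 / (2 * 399))
        assert abs(rule.upper - 1.43) < 3 * se
        assert abs(rule.lower - 1.03) < 3 * se


class TestPositivity:
    rule = sq.CutoffRule(mean=1.0, sd=0.5, upper=1.5, lower=0.5, n=100)

    def _m(self, fi):
        return sq.FluorMetrics(0, "annexin", fi, 0.0, 0.0, 0.0)

    def test_boundary_is_negative(self):
        assert sq.classify_positive(self._m(1.5), self.rule) is False

    def test_above_is_positive(self):
        assert sq.classify_positive(self._m(1.5 + 1e-9), self.rule) is True

    def test_planted_mixture_fraction(self):
        """79% planted above-cutoff spheroids recovered within binomial 3 SE."""
        rng = np.random.default_rng(3)
        n = 400
        positive = rng.random(n) < 0.79
        values = np.where(positive,
                          rng.normal(self.rule.upper + 0.6, 0.05, n),
                          rng.normal(self.rule.upper - 0.6, 0.05, n))
        frac = np.mean([sq.classify_positive(self._m(v), self.rule) for v in values])
        assert abs(frac - 0.79) < 3 * math.sqrt(0.79 * 0.21 / n)


class TestStainingHomogeneity:
    def test_identical_planes_pass(self):
        cv, ok = sq.staining_homogeneity([2.0, 2.0, 2.0])
        assert cv == 0.0 and ok

    def test_two_plane_closed_form_fails(self):
        cv, ok = sq.staining_homogeneity([1.0, 3.0])
        assert cv == pytest.approx(math.sqrt(2) / 2)
        assert not ok

    def test_too_few_planes(self):
        with pytest.raises(ValueError):
            sq.staining_homogeneity([1.0])

    def test_five_percent_jitter_passes(self):
        rng = np.random.default_rng(8)
        means = 10.0 * (1 + rng.normal(0, 0.05, 12))
        cv, ok = sq.staining_homogeneity(means)
        assert ok and 0.01 < cv < 0.08
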