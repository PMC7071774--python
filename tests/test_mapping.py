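"""Maps, ROI selection/registration, tumor means, percent change."""

import math

import numpy as np
import pytest

import dosiflare as df
from dosiflare.chromophores import ChromophoreState
from dosiflare.mapping import ChromophoreMap, MeasurementGrid


def uniform_state(hbo2=20.0, hhb=8.0, water=30.0, lipid=60.0):
    return ChromophoreState.from_concentrations(hbo2, hhb, water, lipid)


def make_map(nx=7, ny=5, day=0, hhb_field=None):
    """Map with optional per-site HHb override (drives TOI contrast)."""
    grid = MeasurementGrid.rectangular(nx, ny)
    states = {}
    for pt in grid.points:
        hhb = 8.0 if hhb_field is None else hhb_field(pt)
        states[pt] = uniform_state(hhb=hhb)
    return ChromophoreMap(grid=grid, states=states, visit_day=day)


def lesion_field(center, contrast=3.0, sigma=1.2):
    def f(pt):
        r2 = (pt[0] - center[0]) ** 2 + (pt[1] - center[1]) ** 2
        return 8.0 * (1 + (contrast - 1) * math.exp(-r2 / (2 * sigma**2)))

    return f


class TestInterpolateMap:
    def test_constant_field_gives_constant_raster(self):
        *_, Z = df.interpolate_map(make_map(), "toi")
        assert np.allclose(Z, Z.flat[0])

    def test_raster_equals_site_values_at_sites(self):
        cmap = make_map(hhb_field=lesion_field((3, 2)))
        X, Y, Z = df.interpolate_map(cmap, "hhb", resolution=10)
        for (x, y), s in cmap.states.items():
            ix = np.argmin(np.abs(X[0] - x))
            iy = np.argmin(np.abs(Y[:, 0] - y))
            assert Z[iy, ix] == pytest.approx(s.hhb, rel=1e-9)

    def test_bump_argmax_within_one_cell(self):
        cmap = make_map(hhb_field=lesion_field((4, 3)))
        X, Y, Z = df.interpolate_map(cmap, "hhb", resolution=10)
        iy, ix = np.unravel_index(np.argmax(Z), Z.shape)
        assert abs(X[iy, ix] - 4) <= 1.0 and abs(Y[iy, ix] - 3) <= 1.0

    def test_no_overshoot(self):
        cmap = make_map(hhb_field=lesion_field((3, 2)))
        vals = [s.hhb for s in cmap.states.values()]
        *_, Z = df.interpolate_map(cmap, "hhb")
        assert Z.max() <= max(vals) + 1e-12 and Z.min() >= min(vals) - 1e-12

    def test_too_few_sites_rejected(self):
        grid = MeasurementGrid.rectangular(3, 3)
        cmap = ChromophoreMap(grid, {(0, 0): uniform_state(), (1, 1): uniform_state()})
        with pytest.raises(ValueError, match=">= 4"):
            df.interpolate_map(cmap, "toi")


class TestSelectROI:
    def test_lesion_contrast_centers_roi(self):
        cmap = make_map(hhb_field=lesion_field((4, 3), contrast=3.0))
        roi = df.select_tumor_roi(cmap, 3.0)
        assert roi.center == (4, 3)
        assert len(roi.members) == 9  # ceil(3/1) = 3 points per axis

    def test_small_tumor_single_point(self):
        cmap = make_map(hhb_field=lesion_field((2, 2)))
        roi = df.select_tumor_roi(cmap, 0.8)
        assert roi.members == ((2, 2),)

    def test_tie_breaks_to_smaller_coordinates(self):
        grid = MeasurementGrid.rectangular(4, 4)
        states = {pt: uniform_state() for pt in grid.points}  # all TOI equal
        cmap = ChromophoreMap(grid, states)
        roi = df.select_tumor_roi(cmap, 1.0)
        assert roi.center == (0, 0)

    def test_extent_clipped_at_grid_edge(self):
        cmap = make_map(hhb_field=lesion_field((0, 0), contrast=5.0))
        roi = df.select_tumor_roi(cmap, 3.0)
        assert roi.center == (0, 0)
        assert all(0 <= x and 0 <= y for x, y in roi.members)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            df.select_tumor_roi(make_map(), 0.0)


class TestRegisterROI:
    def test_identical_followup_zero_shift(self):
        cmap = make_map(hhb_field=lesion_field((3, 2)))
        roi = df.select_tumor_roi(cmap, 3.0)
        shifted = df.register_roi_shift(roi, cmap)
        assert shifted.center == roi.center

    def test_translated_lesion_recovered(self):
        base = make_map(hhb_field=lesion_field((3, 2)))
        roi = df.select_tumor_roi(base, 3.0)
        moved = make_map(hhb_field=lesion_field((4, 2)), day=1)
        shifted = df.register_roi_shift(roi, moved, max_shift=1)
        assert shifted.center == (4, 2)
        assert len(shifted.members) == len(roi.members)

    def test_max_shift_zero_returns_unchanged(self):
        cmap = make_map(hhb_field=lesion_field((3, 2)))
        roi = df.select_tumor_roi(cmap, 3.0)
        assert df.register_roi_shift(roi, cmap, max_shift=0) is roi


class TestTumorMean:
    def test_uniform_roi_returns_that_value(self):
        cmap = make_map()
        roi = df.select_tumor_roi(cmap, 2.0)
        m = df.tumor_mean(cmap, roi)
        assert m.hbo2 == pytest.approx(20.0)
        assert m.toi == pytest.approx(8.0 * 30 / 60)

    def test_two_site_arithmetic(self):
        grid = MeasurementGrid.rectangular(2, 1)
        states = {(0, 0): uniform_state(hbo2=10.0), (1, 0): uniform_state(hbo2=20.0)}
        cmap = ChromophoreMap(grid, states)
        roi = df.TumorROI(center=(0, 0), half_extent=(0, 0), members=((0, 0), (1, 0)))
        assert df.tumor_mean(cmap, roi).hbo2 == pytest.approx(15.0)

    def test_matches_brute_force_on_random_maps(self, rng):
        grid = MeasurementGrid.rectangular(5, 5)
        states = {
            pt: ChromophoreState.from_concentrations(
                rng.uniform(5, 40), rng.uniform(2, 15), rng.uniform(10, 50), rng.uniform(20, 80)
            )
            for pt in grid.points
        }
        cmap = ChromophoreMap(grid, states)
        roi = df.select_tumor_roi(cmap, 3.0)
        m = df.tumor_mean(cmap, roi)
        for c in df.CHROMOPHORES:
            brute = sum(getattr(states[pt], c) for pt in roi.members) / len(roi.members)
            assert getattr(m, c) == pytest.approx(brute, rel=1e-12)

    def test_empty_roi_rejected(self):
        cmap = make_map()
        roi = df.TumorROI(center=(0, 0), half_extent=(0, 0), members=())
        with pytest.raises(ValueError):
            df.tumor_mean(cmap, roi)


class TestPercentChange:
    def test_forty_percent_day1_flare(self):
        # a 20 -> 28 uM oxyhemoglobin rise is the +40% day-1 flare magnitude
        pc = df.percent_change({0: 20.0, 1: 28.0})
        assert pc[1] == pytest.approx(40.0)
        assert pc[0] == 0.0

    def test_no_change_is_zero(self):
        assert df.percent_change({0: 7.0, 3: 7.0})[3] == 0.0

    def test_scale_invariance(self):
        a = df.percent_change({0: 20.0, 1: 23.0, 5: 18.0})
        b = df.percent_change({0: 40.0, 1: 46.0, 5: 36.0})
        for d in a:
            assert a[d] == pytest.approx(b[d], rel=1e-12)

    def test_zero_baseline_warns_nan(self):
        with pytest.warns(UserWarning, match="baseline"):
            pc = df.percent_change({0: 0.0, 1: 5.0})
        assert math.isnan(pc[1])

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            df.percent_change({1: 5.0})
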