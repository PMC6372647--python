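import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import keelquant as kq
from keelquant import morphometry as mm


def brute_force_moments(mask, pixel_size):
    """Independent oracle: explicit sums over pixel centers + extent correction."""
    dy, dx = pixel_size
    pts = [(r * dy, c * dx) for r, c in zip(*np.nonzero(mask))]
    ys = np.array([p[0] for p in pts])
    xs = np.array([p[1] for p in pts])
    cx, cy = xs.mean(), ys.mean()
    mu20 = sum((x - cx) ** 2 for x in xs) / len(xs) + dx * dx / 12
    mu02 = sum((y - cy) ** 2 for y in ys) / len(ys) + dy * dy / 12
    mu11 = sum((x - cx) * (y - cy) for x, y in zip(xs, ys)) / len(xs)
    return len(pts) * dx * dy, (cx, cy), (mu20, mu02, mu11)


class TestRegionMoments:
    def test_solid_square(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 3:7] = True
        area, (cx, cy), _ = mm.region_moments(mask, (1.0, 1.0))
        assert area == 16.0
        assert (cx, cy) == (4.5, 3.5)

    def test_horizontal_line_moments(self):
        """1x5 line at 1 µm pixels: mu20 = 2 + 1/12, mu02 = 1/12, mu11 = 0."""
        mask = np.zeros((3, 7), bool)
        mask[1, 1:6] = True
        _, _, (mu20, mu02, mu11) = mm.region_moments(mask, (1.0, 1.0))
        assert mu20 == pytest.approx(2 + 1 / 12)
        assert mu02 == pytest.approx(1 / 12)
        assert mu11 == 0.0

    @given(dr=st.integers(0, 10), dc=st.integers(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_translation_invariance(self, dr, dc):
        base = np.zeros((30, 30), bool)
        base[3:8, 4:10] = True
        base[5, 10:13] = True
        moved = np.roll(np.roll(base, dr, axis=0), dc, axis=1)
        _, _, m1 = mm.region_moments(base, (0.7, 0.5))
        _, _, m2 = mm.region_moments(moved, (0.7, 0.5))
        assert m1 == pytest.approx(m2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        mask = rng.random((15, 15)) > 0.6
        mask[7, 7] = True
        area, cen, mom = mm.region_moments(mask, (1.05, 0.69))
        area_o, cen_o, mom_o = brute_force_moments(mask, (1.05, 0.69))
        assert area == pytest.approx(area_o)
        assert cen == pytest.approx(cen_o)
        assert mom == pytest.approx(mom_o)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            mm.region_moments(np.zeros((4, 4), bool), (1.0, 1.0))


class TestAxisMetrics:
    def test_diagonal_moments(self):
        major, minor, orient, degen = mm.axis_metrics((4.0, 1.0, 0.0))
        assert (major, minor) == (8.0, 4.0)
        assert orient == 0.0 and not degen

    def test_isotropic_flags_degenerate(self):
        major, minor, orient, degen = mm.axis_metrics((1.0, 1.0, 0.0))
        assert degen and np.isnan(orient)
        assert mm.eccentricity_index(major, minor) == 1.0

    def test_rotated_ellipse_recovery(self):
        """Rasterised 20/10 px ellipse at 30 deg: orientation ±2 deg, ratio ±0.1."""
        yy, xx = np.mgrid[0:101, 0:101] - 50.0
        th = np.deg2rad(30.0)
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        mask = (u / 20.0) ** 2 + (v / 10.0) ** 2 <= 1.0
        _, _, mom = mm.region_moments(mask, (1.0, 1.0))
        major, minor, orient, _ = mm.axis_metrics(mom)
        assert orient == pytest.approx(30.0, abs=2.0)
        assert major / minor == pytest.approx(2.0, abs=0.1)

    def test_solid_rectangle_closed_form(self):
        """30x10 rectangle: the extent correction makes the ratio exactly w/h."""
        mask = np.zeros((20, 40), bool)
        mask[5:15, 5:35] = True
        _, _, mom = mm.region_moments(mask, (1.0, 1.0))
        major, minor, orient, _ = mm.axis_metrics(mom)
        assert mm.eccentricity_index(major, minor) == pytest.approx(3.0, abs=0.05)
        assert orient == 0.0

    @given(rot=st.integers(0, 90))
    @settings(max_examples=20, deadline=None)
    def test_eccentricity_rotation_stable(self, rot):
        yy, xx = np.mgrid[0:121, 0:121] - 60.0
        th = np.deg2rad(rot)
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        mask = (u / 24.0) ** 2 + (v / 12.0) ** 2 <= 1.0
        _, _, mom = mm.region_moments(mask, (1.0, 1.0))
        major, minor, _, _ = mm.axis_metrics(mom)
        assert mm.eccentricity_index(major, minor) == pytest.approx(2.0, rel=0.02)


class TestAnglesAndZones:
    @pytest.mark.parametrize("orient,ap,expected", [
        (30.0, 0.0, 30.0),
        (120.0, 0.0, 60.0),
        (-80.0, 0.0, 80.0),
        (90.0, 90.0, 0.0),
    ])
    def test_alignment_fold(self, orient, ap, expected):
        assert mm.alignment_angle(orient, ap) == pytest.approx(expected)

    def test_alignment_nan_propagates(self):
        assert np.isnan(mm.alignment_angle(float("nan"), 0.0))

    @pytest.mark.parametrize("d,zone", [(10, "medial"), (19.99, "medial"),
                                        (20, "lateral"), (35, "lateral"),
                                        (60, "lateral"), (75, "outside")])
    def test_zone_bounds(self, d, zone):
        assert mm.assign_zone(60.0 + d, 60.0) == zone
        assert mm.assign_zone(60.0 - d, 60.0) == zone


class TestMidline:
    def test_keel_frame_recovers_configured_midline(self):
        # the deepened keel has a left-right symmetric envelope; the flat
        # early plate does not constrain the midline, so measure late frames
        cfg = kq.make_preset("wild_type", seed=2, n_cells=30, duration=150.0,
                             frame_interval=30.0)
        truth = kq.simulate_kinematics(cfg)
        stack = kq.render_transverse_view(truth, cfg)
        frame = stack.channel("membrane")[-1][:, 0, :]
        est = mm.estimate_midline(frame, stack.voxel_size[2])
        assert abs(est.midline_x - cfg.midline_x) <= 3.0

    def test_uniform_frame_falls_back_to_centre(self):
        est = mm.estimate_midline(np.zeros((40, 81)), 1.0)
        assert est.midline_x == pytest.approx(40.0)


class TestMidlineDepth:
    def test_synthetic_slab(self):
        frame = np.zeros((80, 60))
        frame[10:53, :] = 100.0  # slab z in [10, 52] µm at 1 µm voxels
        d = mm.midline_depth(frame, (1.0, 1.0), midline_x=30.0)
        assert d == pytest.approx(42.0, abs=1.0)

    def test_empty_frame_returns_zero(self):
        assert mm.midline_depth(np.zeros((30, 30)), (1.0, 1.0), 15.0) == 0.0


class TestTransverseMetrics:
    def test_vertical_and_horizontal_ellipses(self, small_wt_config):
        from conftest import make_truth_frame

        truth = make_truth_frame([
            dict(x_um=40.0, y_um=30.0, z_um=25.0, long_axis_um=20.0, angle_deg=0.0),
            dict(x_um=80.0, y_um=30.0, z_um=25.0, long_axis_um=20.0, angle_deg=90.0),
        ])
        rec = kq.transverse_cell_metrics(truth, small_wt_config)
        assert rec.loc[rec.cell_id == 0, "angle_deg"].iloc[0] == pytest.approx(0.0, abs=2.0)
        assert rec.loc[rec.cell_id == 1, "angle_deg"].iloc[0] == pytest.approx(90.0, abs=2.0)


class TestAreaSeries:
    def _records(self, areas_by_frame, zone="medial"):
        rows = []
        for tid, areas in areas_by_frame.items():
            for k, a in enumerate(areas):
                rows.append(dict(track_id=tid, frame=k, t_min=2.5 * k,
                                 area_um2=a, x_um=0.0, zone=zone))
        return pd.DataFrame(rows)

    def test_single_cell_series_exact(self):
        series = mm.surface_area_timeseries(self._records({1: [100.0, 80.0, 60.0]}))
        np.testing.assert_allclose(series.mean_area_um2, [100.0, 80.0, 60.0])
        np.testing.assert_allclose(series.normalised_area, [1.0, 0.8, 0.6])

    def test_constant_masks_give_flat_series(self):
        series = mm.surface_area_timeseries(self._records({1: [50.0] * 4, 2: [70.0] * 4}))
        assert (series.mean_area_um2 == 60.0).all()

    def test_zone_frozen_at_first_appearance(self):
        rec = self._records({1: [50.0, 50.0]})
        rec.loc[rec.frame == 1, "zone"] = "lateral"  # cell crosses the boundary
        series = mm.surface_area_timeseries(rec)
        assert set(series.zone) == {"medial"} and len(series) == 2


class TestEventDetection:
    def _shrinking(self, n_frames=13, end=10):
        rows = []
        for k in range(end):
            rows.append(dict(track_id=1, frame=k, t_min=2.5 * k,
                             area_um2=100.0 * (1 - k / 10), x_um=62.0))
        return pd.DataFrame(rows), n_frames

    def test_linear_shrink_gives_one_event(self):
        rec, nf = self._shrinking()
        ev = mm.detect_internalisation_events(rec, midline_x=60.0, n_frames=nf)
        assert len(ev) == 1
        # first frame below 20 % of 100 µm²
        assert ev.event_time_min.iloc[0] == pytest.approx(2.5 * 9, abs=2.6)
        assert ev.abs_x_um.iloc[0] == pytest.approx(2.0)

    def test_loss_at_movie_end_is_censored(self):
        rec, _ = self._shrinking(n_frames=10, end=10)
        ev = mm.detect_internalisation_events(rec, midline_x=60.0, n_frames=10)
        assert len(ev) == 0
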