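import dataclasses

import numpy as np
import pandas as pd
import pytest

import keelquant as kq
from keelquant.io_core import ConfigurationError
from keelquant.synthetic_tissue import _weighted_voronoi_frame, dorsal_run_config

from conftest import make_truth_frame


class TestPresets:
    def test_wild_type_depth_anchors(self):
        cfg = kq.make_preset("wild_type")
        assert cfg.initial_depth == 42.0 and cfg.final_depth == 138.0
        assert cfg.constriction_rate == 0.5 and cfg.myosin_ml_profile == "peaked"

    def test_cdh2_preset(self):
        cfg = kq.make_preset("cdh2_deficient")
        assert cfg.final_depth == 85.0
        assert cfg.myosin_ml_profile == "flat"
        assert cfg.ectopic_event_rate > 0
        assert cfg.convergence_speed < kq.make_preset("wild_type").convergence_speed

    def test_myosin_inhibited_preset(self):
        cfg = kq.make_preset("myosin_inhibited")
        assert cfg.constriction_rate == 0.0
        # no deepening: the prescribed midline depth trajectory is constant
        t = cfg.times()
        assert np.allclose(cfg.midline_depth_at(t), cfg.initial_depth)

    def test_unknown_preset(self):
        with pytest.raises(ConfigurationError):
            kq.make_preset("mystery_fish")

    def test_wild_type_depth_trajectory_monotone(self):
        cfg = kq.make_preset("wild_type")
        d = cfg.midline_depth_at(cfg.times())
        assert np.all(np.diff(d) >= 0)
        assert d[0] == 42.0 and d[-1] == pytest.approx(138.0)


class TestKinematics:
    def test_zero_rates_freeze_centroids(self):
        cfg = kq.make_preset(
            "wild_type", n_cells=10, duration=20.0, frame_interval=5.0,
            convergence_speed=0.0, anterior_drift_speed=0.0, constriction_rate=0.0,
            position_jitter_sd=0.0, internalisation_onset=100.0,
        )
        truth = kq.simulate_kinematics(cfg)
        for col in ("x_um", "y_um", "dorsal_area_um2"):
            per_cell = truth.groupby("cell_id")[col].nunique()
            assert (per_cell == 1).all(), col

    def test_medial_area_halves_per_hour(self):
        """Prescribed medial dorsal areas fall ~50% over 60 min of constriction."""
        cfg = dorsal_run_config(kq.make_preset("wild_type", seed=11, n_cells=120))
        truth = kq.simulate_kinematics(cfg)
        mid = cfg.midline_x
        f0 = truth[truth.frame == 0]
        medial_ids = f0[(f0.x_um - mid).abs() < 20]["cell_id"]
        last = truth.frame.max()
        a0 = f0[f0.cell_id.isin(medial_ids)].dorsal_area_um2.mean()
        a1 = truth[(truth.frame == last) & truth.cell_id.isin(medial_ids)].dorsal_area_um2.mean()
        assert a1 / a0 == pytest.approx(0.5, abs=0.05)

    def test_wild_type_events_confined_to_medial_zone(self):
        cfg = dorsal_run_config(kq.make_preset("wild_type", seed=5), duration=240.0)
        truth = kq.simulate_kinematics(cfg)
        ev = truth[truth.internalised].groupby("cell_id").first()
        assert len(ev) > 5
        assert ((ev.x_um - cfg.midline_x).abs() <= 20).all()

    def test_cdh2_event_positions_uniform_over_plate_width(self):
        """Ectopic event |x| passes a KS uniformity check on [0, 60] µm.

        The KS distance is computed directly from the empirical CDF (no
        library test) and compared with the 5% critical value.
        """
        for seed in (1, 2):
            cfg = dorsal_run_config(kq.make_preset("cdh2_deficient", seed=seed), duration=240.0)
            truth = kq.simulate_kinematics(cfg)
            ev = truth[truth.internalised].groupby("cell_id").first()
            x = np.sort(np.clip((ev.x_um - cfg.midline_x).abs() / 60.0, 0, 1))
            n = len(x)
            assert n >= 35
            ecdf_hi = np.arange(1, n + 1) / n
            ecdf_lo = np.arange(0, n) / n
            d = max(np.abs(ecdf_hi - x).max(), np.abs(x - ecdf_lo).max())
            assert d < 1.358 / np.sqrt(n)  # p > 0.05

    def test_cell_ids_conserved_every_frame(self, small_wt_truth, small_wt_config):
        counts = small_wt_truth.groupby("frame")["cell_id"].nunique()
        assert (counts == small_wt_config.n_cells).all()

    def test_area_non_increasing_after_onset(self, small_wt_truth):
        for _, g in small_wt_truth.groupby("cell_id"):
            a = g.sort_values("frame")["dorsal_area_um2"].to_numpy()
            assert np.all(np.diff(a) <= 1e-9)

    def test_determinism_same_seed(self, small_wt_config):
        t1 = kq.simulate_kinematics(small_wt_config)
        t2 = kq.simulate_kinematics(small_wt_config)
        pd.testing.assert_frame_equal(t1, t2)


class TestDorsalRender:
    def test_two_cell_boundary_is_perpendicular_bisector(self):
        # half-integer centers put the bisector between pixel columns
        labels, realised, _ = _weighted_voronoi_frame(
            centers_px=np.array([[30.0, 20.5], [30.0, 40.5]]),
            target_areas_px=np.array([500.0, 500.0]),
            shape=(61, 61),
        )
        # symmetric layout: realised areas equal within 2 %
        assert abs(realised[0] - realised[1]) / realised.mean() < 0.02
        # cells split at the bisector x = 30.5
        left = labels[:, :31]
        right = labels[:, 31:]
        assert set(np.unique(left[left > 0])) == {1}
        assert set(np.unique(right[right > 0])) == {2}

    def test_realised_areas_match_prescription(self, dorsal_render):
        _, _, _, _, realised = dorsal_render
        f0 = realised[realised.frame == 0]
        rel = (f0.realised_area_um2 - f0.target_area_um2).abs() / f0.target_area_um2
        assert rel.median() <= 0.10

    def test_render_deterministic(self, dorsal_render):
        cfg, truth, stack, _, _ = dorsal_render
        again = kq.render_dorsal_view(truth, cfg)
        np.testing.assert_array_equal(stack.data, again.data)


class TestTransverseRender:
    def test_myosin_depth_decay_is_exponential(self):
        """Noise-free myosin at one decay length below the surface is e^-1 of
        the surface value."""
        cfg = kq.make_preset("wild_type", n_cells=4, duration=5.0, frame_interval=5.0,
                             noise_sd=0.0, background=0.0)
        truth = make_truth_frame(
            [dict(x_um=60.0, y_um=30.0, z_um=20.0)], frame=0)
        truth = pd.concat([truth, truth.assign(frame=1, t_min=5.0)], ignore_index=True)
        stack = kq.render_transverse_view(truth, cfg)
        myo = stack.channel("myosin")[0][:, 0, :].astype(float)
        dz = stack.voxel_size[0]
        col = int(cfg.midline_x / stack.voxel_size[2])
        surf_row = int(np.ceil(cfg.tissue_top / dz))
        decay_row = surf_row + int(round(cfg.myosin_dv_decay / dz))
        surf_depth = surf_row * dz - cfg.tissue_top
        decay_depth = decay_row * dz - cfg.tissue_top
        expected = np.exp(-(decay_depth - surf_depth) / cfg.myosin_dv_decay)
        assert myo[decay_row, col] / myo[surf_row, col] == pytest.approx(expected, rel=0.02)

    def test_surface_myosin_medially_enriched(self, transverse_render):
        cfg, _, stack = transverse_render
        myo = stack.channel("myosin")[0][:, 0, :].astype(float)
        dz, dx = stack.voxel_size[0], stack.voxel_size[2]
        surf = int(np.ceil(cfg.tissue_top / dz)) + 1
        x = np.arange(myo.shape[1]) * dx
        medial = myo[surf, np.abs(x - cfg.midline_x) <= 20].mean()
        lateral = myo[surf, (np.abs(x - cfg.midline_x) >= 40) & (np.abs(x - cfg.midline_x) <= 60)].mean()
        assert medial > lateral

    def test_frame0_tissue_depth_equals_initial_depth(self, transverse_render):
        cfg, _, stack = transverse_render
        mem = stack.channel("membrane")[0][:, 0, :].astype(float)
        dz = stack.voxel_size[0]
        col = int(cfg.midline_x / stack.voxel_size[2])
        rows = np.nonzero(mem[:, col] > 0.25 * mem[:, col].max())[0]
        measured = (rows[-1] - rows[0]) * dz
        assert measured == pytest.approx(cfg.initial_depth, abs=1.5 * dz)


class TestNucleiRender:
    def test_blob_centroid_matches_truth(self):
        cfg = kq.make_preset("wild_type", noise_sd=0.0, background=0.0)
        truth = make_truth_frame([dict(x_um=40.3, y_um=30.7, z_um=25.4)])
        stack = kq.render_nuclei_view(truth, cfg)
        vol = stack.data[0].astype(float)
        dz, dy, dx = stack.voxel_size
        zz, yy, xx = np.mgrid[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
        total = vol.sum()
        cz, cy, cx = (vol * zz).sum() / total, (vol * yy).sum() / total, (vol * xx).sum() / total
        assert abs(cx * dx - 40.3) < dx and abs(cy * dy - 30.7) < dy and abs(cz * dz - 25.4) < dz

    def test_zero_cells_gives_background_stack(self):
        cfg = kq.make_preset("wild_type", noise_sd=0.0)
        stack = kq.render_nuclei_view(make_truth_frame([]), cfg)
        assert np.all(stack.data == int(cfg.background))

    def test_two_separated_nuclei_give_two_maxima(self):
        cfg = kq.make_preset("wild_type", noise_sd=0.0, background=0.0)
        sep = 10 * cfg.nucleus_sigma
        truth = make_truth_frame([
            dict(x_um=40.0, y_um=30.0, z_um=20.0),
            dict(x_um=40.0 + sep, y_um=30.0, z_um=20.0),
        ])
        stack = kq.render_nuclei_view(truth, cfg)
        from skimage.feature import peak_local_max

        peaks = peak_local_max(stack.data[0].astype(float), min_distance=3, threshold_abs=50)
        assert len(peaks) == 2
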