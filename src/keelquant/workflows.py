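"""End-to-end analysis workflows at desk scale.

Each function generates a synthetic movie for one experimental condition,
runs the relevant pipeline stages on the *rendered* data (never on the ground
truth, except where the measurement is defined on truth ellipses) and returns
the recovered summary quantities. These are the parameter-recovery runs that
validate the pipeline against the values its generator was anchored to.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import morphometry as mm
from . import profiles_stats as ps
from . import segmentation as seg
from . import synthetic_tissue as syn
from . import tracking as trk


def transverse_run(preset: str, seed: int, frame_interval: float = 5.0) -> dict:
    """Transverse-view run: midline depth at first/last frame and the
    moment-based long-axis angle summaries.

    Depths are measured on the rendered membrane channel; angles by
    rasterising each cell at the acquisition calibration and measuring it
    with the same moment pipeline used for segmented data.
    """
    cfg = syn.make_preset(preset, seed=seed, frame_interval=frame_interval)
    truth = syn.simulate_kinematics(cfg)
    stack = syn.render_transverse_view(truth, cfg)
    mem = stack.channel("membrane")
    voxel_zx = (stack.voxel_size[0], stack.voxel_size[2])

    def depth(k):
        return mm.midline_depth(mem[k][:, 0, :], voxel_zx, cfg.midline_x)

    n_pre = int(cfg.internalisation_onset / cfg.frame_interval)
    last = int(truth["frame"].max())
    early = mm.transverse_cell_metrics(truth, cfg, frames=list(range(n_pre)))
    late = mm.transverse_cell_metrics(truth, cfg, frames=[last - 2, last - 1, last])
    in_plate = early[early.zone != "outside"]
    return {
        "config": cfg,
        "first_depth": depth(0),
        "final_depth": depth(stack.n_frames - 1),
        "early_angle": float(in_plate.angle_deg.mean()),
        "late_medial_angle": float(late[late.zone == "medial"].angle_deg.mean()),
        "late_lateral_angle": float(late[late.zone == "lateral"].angle_deg.mean()),
    }


def _segment_and_link(stack) -> tuple[pd.DataFrame, int]:
    frames, _ = seg.select_tangential_plane(stack)
    masks = seg.segment_movie(
        frames, (stack.voxel_size[1], stack.voxel_size[2]), stack.frame_interval
    )
    records = trk.link_label_masks(masks)
    return records, len(masks)


def dorsal_constriction_run(seed: int, preset: str = "wild_type", duration: float = 60.0) -> dict:
    """Dorsal tangential run: per-zone mean-area time series via segmentation.

    Returns the final/initial mean-area ratios of the medial and lateral
    cohorts over ``duration`` minutes of constriction.
    """
    cfg = syn.dorsal_run_config(syn.make_preset(preset, seed=seed), duration=duration)
    truth = syn.simulate_kinematics(cfg)
    stack = syn.render_dorsal_view(truth, cfg)
    records, _ = _segment_and_link(stack)
    records["zone"] = [mm.assign_zone(x, cfg.midline_x) for x in records["x_um"]]
    series = mm.surface_area_timeseries(records)
    out = {"config": cfg, "series": series}
    for zone in ("medial", "lateral"):
        z = series[series.zone == zone].sort_values("frame")
        out[f"{zone}_final_ratio"] = float(z.normalised_area.iloc[-1]) if len(z) else np.nan
    return out


def dorsal_event_run(preset: str, seed: int, duration: float = 240.0) -> pd.DataFrame:
    """Long dorsal run for internalisation-event detection.

    Returns the detected event table (|x| from the midline, times).
    """
    cfg = syn.dorsal_run_config(syn.make_preset(preset, seed=seed), duration=duration)
    cfg = dataclasses.replace(cfg, frame_interval=5.0)
    truth = syn.simulate_kinematics(cfg)
    stack = syn.render_dorsal_view(truth, cfg)
    records, n_frames = _segment_and_link(stack)
    return mm.detect_internalisation_events(records, cfg.midline_x, n_frames=n_frames)


def nuclei_tracking_run(seed: int, duration: float = 50.0) -> dict:
    """Nuclei render -> LoG detection -> linking, scored against ground truth.

    Returns detection recall/precision (match radius 2·sigma) and the fraction
    of ground-truth trajectories recovered with >= 80 % correctly linked steps
    (match radius 2 µm).
    """
    from scipy.spatial import cKDTree

    cfg = syn.make_preset("wild_type", seed=seed)
    cfg = dataclasses.replace(cfg, duration=duration)
    truth = syn.simulate_kinematics(cfg)
    stack = syn.render_nuclei_view(truth, cfg)
    det = seg.detect_nuclei_movie(stack)

    rad = 2 * cfg.nucleus_sigma
    recalls, precisions = [], []
    for k in range(stack.n_frames):
        tp = truth[truth.frame == k][["x_um", "y_um", "z_um"]].to_numpy()
        dp = det[det.frame == k][["x_um", "y_um", "z_um"]].to_numpy()
        if len(dp) == 0:
            recalls.append(0.0)
            precisions.append(0.0)
            continue
        recalls.append(float((cKDTree(dp).query(tp)[0] < rad).mean()))
        precisions.append(float((cKDTree(tp).query(dp)[0] < rad).mean()))

    tracks = trk.link_tracks(det, max_disp=5.0)
    real = tracks[~tracks.imputed]
    by_frame = {k: g for k, g in real.groupby("frame")}
    n_frames = stack.n_frames
    recovered = 0
    for _, g in truth.groupby("cell_id"):
        tids = []
        for _, row in g.sort_values("frame").iterrows():
            dk = by_frame.get(int(row.frame))
            if dk is None or len(dk) == 0:
                tids.append(-1)
                continue
            d = np.linalg.norm(
                dk[["x_um", "y_um", "z_um"]].to_numpy() - row[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                axis=1,
            )
            i = int(np.argmin(d))
            tids.append(int(dk.track_id.iloc[i]) if d[i] < 2.0 else -1)
        good_steps = sum(1 for a, b in zip(tids[:-1], tids[1:]) if a == b and a >= 0)
        if good_steps >= 0.8 * (n_frames - 1):
            recovered += 1
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "track_recovery": recovered / cfg.n_cells,
    }


def reporter_profile_run(preset: str, seed: int, duration: float = 90.0) -> dict:
    """Myosin/actin profile run on a transverse render.

    Returns mediolateral enrichment ratios (mean 0-20 µm over 40-60 µm from
    the midline, at the tissue surface) and depth steepness indices (mean
    0-5 µm over 20-40 µm below the surface) for both reporter channels,
    measured at mid-movie with image-estimated background.
    """
    cfg = syn.make_preset(preset, seed=seed, frame_interval=5.0)
    cfg = dataclasses.replace(cfg, duration=duration)
    truth = syn.simulate_kinematics(cfg)
    stack = syn.render_transverse_view(truth, cfg)
    voxel_zx = (stack.voxel_size[0], stack.voxel_size[2])
    k = stack.n_frames // 2
    membrane = stack.channel("membrane")[k][:, 0, :]
    out = {"config": cfg}
    for ch in ("myosin", "actin"):
        img = stack.channel(ch)[k][:, 0, :]
        background = float(np.percentile(img[:4], 50))  # empty rows above the tissue
        band = ps.surface_band_image(img, voxel_zx, surface_frame=membrane)
        ml = ps.ml_profile(np.nan_to_num(band), voxel_zx[1], cfg.midline_x, background=background)
        surf_z = ps.locate_surface(membrane, voxel_zx[0])
        dv = ps.dv_profile(img, voxel_zx, surface_z_um=surf_z, background=background)
        out[f"{ch}_ml_ratio"] = ml.summary_ratio
        out[f"{ch}_dv_steepness"] = dv.summary_ratio
    return out
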