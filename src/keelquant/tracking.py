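"""Frame-to-frame linking of detections and trajectory statistics.

Linking solves an optimal bipartite assignment per frame pair (total squared
displacement minimised, links above ``max_disp`` rejected). Unmatched
detections start new tracks; track ends may bridge up to ``memory_frames``
missed frames, with gap positions linearly interpolated and flagged imputed.
The procedure is deterministic and invariant to detection input order (ties
broken by smallest index).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .morphometry import assign_zone


def link_tracks(
    detections: pd.DataFrame,
    max_disp: float,
    memory_frames: int = 1,
) -> pd.DataFrame:
    """Link per-frame detections into tracks.

    ``detections`` needs columns frame, x_um, y_um, z_um (z may be 0 for 2D
    data); any extra columns are carried through. Returns the same rows plus
    track_id and imputed=False, with imputed gap rows inserted where a track
    bridged missed frames.
    """
    req = {"frame", "x_um", "y_um", "z_um"}
    if not req.issubset(detections.columns):
        raise ValueError(f"detections must have columns {sorted(req)}")
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = np.arange(int(det["frame"].min()), int(det["frame"].max()) + 1)

    # active track ends: (track_id, last_frame, position)
    next_id = 0
    track_of_row = np.full(len(det), -1, dtype=int)
    open_ends: list[dict] = []
    imputed_rows = []

    by_frame = {int(f): grp for f, grp in det.groupby("frame")}
    for f in frames:
        grp = by_frame.get(int(f))
        if grp is None:
            continue
        idx = grp.index.to_numpy()
        pos = grp[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

        candidates = [e for e in open_ends if 1 <= f - e["frame"] <= 1 + memory_frames]
        assigned_rows = set()
        if candidates and len(pos):
            cpos = np.array([e["pos"] for e in candidates])
            gap = np.array([f - e["frame"] for e in candidates])
            d2 = ((cpos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            # reject links beyond max_disp per bridged frame
            limit2 = (max_disp * gap[:, None]) ** 2
            big = 1e12
            cost = np.where(d2 <= limit2, d2, big)
            ri, ci = linear_sum_assignment(cost)
            for i, j in zip(ri, ci):
                if cost[i, j] >= big:
                    continue
                e = candidates[i]
                row = idx[j]
                track_of_row[row] = e["track_id"]
                assigned_rows.add(row)
                # interpolate bridged frames
                for g in range(1, f - e["frame"]):
                    alpha = g / (f - e["frame"])
                    p = (1 - alpha) * np.asarray(e["pos"]) + alpha * pos[j]
                    imputed_rows.append({
                        "frame": e["frame"] + g, "x_um": p[0], "y_um": p[1],
                        "z_um": p[2], "track_id": e["track_id"], "imputed": True,
                    })
                e["frame"] = int(f)
                e["pos"] = pos[j]
                e["matched"] = True

        open_ends = [e for e in open_ends if e.get("matched") or f - e["frame"] <= memory_frames]
        for e in open_ends:
            e["matched"] = False
        for j, row in enumerate(idx):
            if row in assigned_rows:
                continue
            track_of_row[row] = next_id
            open_ends.append({"track_id": next_id, "frame": int(f), "pos": pos[j], "matched": False})
            next_id += 1

    out = det.copy()
    out["track_id"] = track_of_row
    out["imputed"] = False
    if imputed_rows:
        out = pd.concat([out, pd.DataFrame(imputed_rows)], ignore_index=True)
    out = out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return out


def track_table(
    tracks: pd.DataFrame, frame_interval: float, midline_x: float
) -> pd.DataFrame:
    """Annotate linked tracks with per-step displacement, speed and start zone."""
    out = tracks.sort_values(["track_id", "frame"]).copy()
    for ax in ("x_um", "y_um", "z_um"):
        out[f"d{ax[0]}"] = out.groupby("track_id")[ax].diff()
    dt = out.groupby("track_id")["frame"].diff() * frame_interval
    disp = np.sqrt(out["dx"] ** 2 + out["dy"] ** 2 + out["dz"] ** 2)
    out["step_speed"] = disp / dt
    first = out.groupby("track_id")["x_um"].first()
    out["zone0"] = out["track_id"].map(
        lambda tid: assign_zone(first[tid], midline_x)
    )
    return out


def track_speeds(track: pd.DataFrame, frame_interval: float, smoothing_window: int = 3) -> np.ndarray:
    """Centered moving-average step speeds (µm/min) of one track.

    Imputed steps (either endpoint imputed) are excluded before smoothing.
    """
    trk = track.sort_values("frame")
    if len(trk) < 2:
        raise ValueError("track_speeds: track must have at least 2 samples")
    pos = trk[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    fr = trk["frame"].to_numpy()
    imput = trk["imputed"].to_numpy() if "imputed" in trk else np.zeros(len(trk), bool)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1) / (np.diff(fr) * frame_interval)
    keep = ~(imput[:-1] | imput[1:])
    speeds = steps[keep]
    if smoothing_window <= 1 or speeds.size == 0:
        return speeds
    w = min(smoothing_window, speeds.size)
    kernel = np.ones(w) / w
    pad = np.pad(speeds, (w // 2, w - 1 - w // 2), mode="edge")
    return np.convolve(pad, kernel, mode="valid")


def direction_components(track: pd.DataFrame, frame_interval: float, midline_x: float) -> pd.DataFrame:
    """Per-step signed velocity components (µm/min) of one track.

    medial: toward the midline along x; inward: along +z (ventral); anterior:
    along −y (the AP axis maps to image y with anterior at low y).
    """
    trk = track.sort_values("frame")
    if len(trk) < 2:
        raise ValueError("direction_components: track must have at least 2 samples")
    pos = trk[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    fr = trk["frame"].to_numpy()
    dt = np.diff(fr) * frame_interval
    d = np.diff(pos, axis=0)
    toward_mid = np.sign(midline_x - pos[:-1, 0])
    toward_mid[toward_mid == 0] = 1.0
    return pd.DataFrame({
        "frame": fr[1:],
        "medial": toward_mid * d[:, 0] / dt,
        "inward": d[:, 2] / dt,
        "anterior": -d[:, 1] / dt,
    })


def neighbour_distance(detections: pd.DataFrame) -> float:
    """Mean 3D nearest-neighbour distance (µm) among one frame's detections."""
    pts = detections[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if len(pts) < 2:
        raise ValueError("neighbour_distance needs at least 2 detections")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return float(dist[:, 1].mean())


def zone_speed_summary(
    tracks: pd.DataFrame, frame_interval: float, midline_x: float,
    time_bins: np.ndarray,
) -> pd.DataFrame:
    """Mean step speed ± SEM per start zone per time bin.

    ``time_bins`` are bin edges in minutes. Zones are fixed at track start.
    Empty zone/bin combinations appear with NaN mean.
    """
    from .profiles_stats import sem

    tab = track_table(tracks, frame_interval, midline_x)
    tab = tab.dropna(subset=["step_speed"])
    if "imputed" in tab:
        tab = tab[~tab["imputed"]]
    tab["t_min"] = tab["frame"] * frame_interval
    tab["bin"] = pd.cut(tab["t_min"], bins=time_bins, include_lowest=True)
    rows = []
    for zone in sorted(tab["zone0"].unique()):
        for interval in tab["bin"].cat.categories:
            grp = tab[(tab["zone0"] == zone) & (tab["bin"] == interval)]
            rows.append({
                "zone": zone,
                "t_bin_centre": interval.mid,
                "mean_speed": grp["step_speed"].mean() if len(grp) else np.nan,
                "sem_speed": sem(grp["step_speed"].to_numpy()) if len(grp) >= 2 else np.nan,
                "n_steps": len(grp),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Label-mask linkage (dorsal movies)
# ---------------------------------------------------------------------------

def link_label_masks(masks, max_disp: float = 6.0, memory_frames: int = 1) -> pd.DataFrame:
    """Link per-frame :class:`~keelquant.segmentation.LabelMask` objects.

    Uses centroid-based assignment (same linker as nuclei) and returns one
    record per cell per frame: track_id, frame, t_min, cell_label, area_um2,
    x_um, y_um, zone is *not* assigned here (midline unknown at this stage).
    """
    from .morphometry import region_moments

    rows = []
    for k, mask in enumerate(masks):
        for lab in range(1, mask.n_cells + 1):
            region = mask.labels == lab
            if not region.any():
                continue
            area, (cx, cy), _ = region_moments(region, mask.pixel_size)
            rows.append({
                "frame": k, "t_min": mask.time_min, "cell_label": lab,
                "x_um": cx, "y_um": cy, "z_um": 0.0, "area_um2": area,
            })
    det = pd.DataFrame(rows)
    if det.empty:
        return det
    linked = link_tracks(det, max_disp=max_disp, memory_frames=memory_frames)
    return linked[~linked["imputed"]].reset_index(drop=True)
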