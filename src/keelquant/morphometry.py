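"""Moment-based cell-shape metrics, zone assignment, midline depth and
internalisation-event detection.

Shape metrics follow the equivalent-ellipse convention: the second central
moments of a region's pixel centres (plus a ``pixel²/12`` extent correction on
the diagonal terms, so a single pixel has a finite minor axis) define a 2×2
covariance whose eigenvalues λ₁ ≥ λ₂ give axis lengths ``4·√λ``. The
eccentricity index is major/minor (≥ 1) and orientation-independent; the
alignment angle is the absolute angle between the major axis and a reference
embryo axis, folded into [0°, 90°].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import MidlineFrame
from .synthetic_tissue import KinematicConfig, MEDIAL_HALFWIDTH, LATERAL_MAX

log = logging.getLogger("keelquant")

_DEGENERATE_RTOL = 1e-9


# ---------------------------------------------------------------------------
# Second-order moments and the equivalent ellipse
# ---------------------------------------------------------------------------

def region_moments(
    mask: np.ndarray, pixel_size: tuple[float, float]
) -> tuple[float, tuple[float, float], tuple[float, float, float]]:
    """Area, centroid and second central moments of a 2D pixel region.

    ``mask`` is a boolean array indexed (row, col); pixel centres sit at
    ``(row·dy, col·dx)`` µm. Returns ``(area_um2, (cx, cy), (mu20, mu02,
    mu11))`` where mu20 is the x (column-axis) variance including the
    ``dx²/12`` pixel-extent correction, mu02 the corrected y variance and
    mu11 the xy covariance, all in µm².
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("region_moments: empty region")
    dy, dx = pixel_size
    xs = cols * dx
    ys = rows * dy
    area = rows.size * dx * dy
    cx, cy = xs.mean(), ys.mean()
    mu20 = ((xs - cx) ** 2).mean() + dx * dx / 12.0
    mu02 = ((ys - cy) ** 2).mean() + dy * dy / 12.0
    mu11 = ((xs - cx) * (ys - cy)).mean()
    return float(area), (float(cx), float(cy)), (float(mu20), float(mu02), float(mu11))


def axis_metrics(
    moments: tuple[float, float, float]
) -> tuple[float, float, float, bool]:
    """Equivalent-ellipse axes from second central moments.

    Returns ``(major_um, minor_um, orientation_deg, degenerate)`` with axis
    lengths ``4·√λ`` and the orientation of the major eigenvector relative to
    the +x axis in (−90°, 90°]. Isotropic regions are flagged degenerate and
    get orientation NaN.
    """
    mu20, mu02, mu11 = moments
    tr = mu20 + mu02
    det = mu20 * mu02 - mu11 * mu11
    disc = max((mu20 - mu02) ** 2 / 4.0 + mu11 * mu11, 0.0)
    root = np.sqrt(disc)
    lam1 = tr / 2.0 + root
    lam2 = tr / 2.0 - root
    if lam2 <= 0 or det <= 0:
        raise ValueError("axis_metrics: moment matrix is not positive definite")
    major = 4.0 * np.sqrt(lam1)
    minor = 4.0 * np.sqrt(lam2)
    degenerate = (lam1 - lam2) <= _DEGENERATE_RTOL * max(lam1, 1e-300)
    if degenerate:
        orientation = float("nan")
    else:
        orientation = np.degrees(0.5 * np.arctan2(2.0 * mu11, mu20 - mu02))
        if orientation <= -90.0:
            orientation += 180.0
    return float(major), float(minor), float(orientation), bool(degenerate)


def eccentricity_index(major: float, minor: float) -> float:
    """Major/minor axis ratio (≥ 1)."""
    if minor <= 0:
        raise ValueError("eccentricity_index: minor axis must be > 0")
    return float(major) / float(minor)


def alignment_angle(orientation_deg: float, ap_axis_deg: float) -> float:
    """Absolute angle between an axis orientation and the AP axis, in [0, 90].

    Axes are head-less, so the difference is folded modulo 180° and then
    reflected into the first quadrant. NaN propagates (degenerate regions).
    """
    if np.isnan(orientation_deg):
        return float("nan")
    delta = abs((orientation_deg - ap_axis_deg) % 180.0)
    return float(min(delta, 180.0 - delta))


def assign_zone(
    centroid_x: float,
    midline_x: float,
    medial_halfwidth: float = MEDIAL_HALFWIDTH,
    lateral_max: float = LATERAL_MAX,
) -> str:
    """Medial (< 20 µm from the midline), lateral (20-60 µm) or outside."""
    d = abs(centroid_x - midline_x)
    if d < medial_halfwidth:
        return "medial"
    if d <= lateral_max:
        return "lateral"
    return "outside"


# ---------------------------------------------------------------------------
# Midline estimation and depth
# ---------------------------------------------------------------------------

def estimate_midline(
    frame: np.ndarray,
    dx: float,
    search_frac: tuple[float, float] = (0.25, 0.75),
    score_floor: float = 0.2,
) -> MidlineFrame:
    """Estimate the mediolateral midline by left-right reflection symmetry.

    For each candidate column the frame is mirrored about it and the Pearson
    correlation of the overlapping halves is scored; the best-scoring column
    wins. Falls back to the frame centre (with a warning) when no candidate
    reaches ``score_floor``.
    """
    img = frame.astype(np.float64)
    if img.ndim != 2:
        raise ValueError("estimate_midline expects a 2D frame")
    n = img.shape[1]
    lo = int(search_frac[0] * n)
    hi = int(search_frac[1] * n)
    best_c, best_score = None, -np.inf
    centred = img - img.mean()
    for c in range(lo, hi):
        w = min(c, n - 1 - c)
        if w < 4:
            continue
        left = centred[:, c - w : c]
        right = centred[:, c + 1 : c + 1 + w][:, ::-1]
        denom = np.sqrt((left ** 2).sum() * (right ** 2).sum())
        score = (left * right).sum() / denom if denom > 0 else 0.0
        if score > best_score:
            best_score, best_c = score, c
    if best_c is None or best_score < score_floor:
        log.warning("midline symmetry score %.2f below floor; using frame centre", best_score)
        return MidlineFrame(midline_x=(n - 1) / 2.0 * dx, source="estimated", score=float(best_score))
    return MidlineFrame(midline_x=best_c * dx, source="estimated", score=float(best_score))


def midline_depth(
    frame: np.ndarray,
    voxel_size_zx: tuple[float, float],
    midline_x: float,
    column_halfwidth: float = 5.0,
    threshold_frac: float = 0.2,
    smoothing_sigma: float = 0.5,
) -> float:
    """Tissue depth (µm) at the midline of a transverse (z, x) frame.

    Within a ±``column_halfwidth`` band around ``midline_x`` the tissue mask is
    pixels above ``threshold_frac`` of the band's robust maximum (99th
    percentile) after Gaussian smoothing; the depth is the z distance between
    the top-most and bottom-most mask rows. Empty mask returns 0 with a
    warning.
    """
    dz, dx = voxel_size_zx
    img = ndimage.gaussian_filter(
        frame.astype(np.float64), sigma=(smoothing_sigma / dz, smoothing_sigma / dx)
    )
    c0 = max(int(round((midline_x - column_halfwidth) / dx)), 0)
    c1 = min(int(round((midline_x + column_halfwidth) / dx)) + 1, img.shape[1])
    band = img[:, c0:c1]
    robust_max = np.percentile(band, 99)
    mask_rows = np.nonzero((band > threshold_frac * robust_max).any(axis=1))[0]
    if mask_rows.size == 0:
        log.warning("midline_depth: empty tissue mask; returning 0")
        return 0.0
    return float((mask_rows[-1] - mask_rows[0]) * dz)


def depth_series(
    stack,
    midline_x: float,
    channel: str = "membrane",
    **kwargs,
) -> pd.DataFrame:
    """Per-frame midline depth of a transverse stack (DataFrame: frame, t_min, depth_um)."""
    data = stack.channel(channel)
    rows = []
    for k in range(data.shape[0]):
        frame = data[k][:, 0, :] if data[k].shape[1] == 1 else data[k].max(axis=1)
        d = midline_depth(frame, (stack.voxel_size[0], stack.voxel_size[2]), midline_x, **kwargs)
        rows.append((k, k * stack.frame_interval, d))
    return pd.DataFrame(rows, columns=["frame", "t_min", "depth_um"])


# ---------------------------------------------------------------------------
# Dorsal profile records
# ---------------------------------------------------------------------------

def profile_records(
    mask_labels: np.ndarray,
    pixel_size: tuple[float, float],
    frame: int,
    time_min: float,
    midline_x: float,
    ap_axis_deg: float = 90.0,
) -> pd.DataFrame:
    """Per-cell dorsal-surface records for one label mask.

    The AP axis of the embryo maps to the image y axis (+90° from +x), so the
    default ``ap_axis_deg`` is 90. Columns: frame, t_min, cell_label, area_um2,
    major_um, minor_um, eccentricity_index, alignment_deg, x_um, y_um, zone,
    degenerate.
    """
    rows = []
    for lab in range(1, int(mask_labels.max()) + 1):
        region = mask_labels == lab
        if not region.any():
            continue
        area, (cx, cy), mom = region_moments(region, pixel_size)
        major, minor, orient, degen = axis_metrics(mom)
        rows.append({
            "frame": frame,
            "t_min": time_min,
            "cell_label": lab,
            "area_um2": area,
            "major_um": major,
            "minor_um": minor,
            "eccentricity_index": eccentricity_index(major, minor),
            "alignment_deg": alignment_angle(orient, ap_axis_deg),
            "x_um": cx,
            "y_um": cy,
            "zone": assign_zone(cx, midline_x),
            "degenerate": degen,
        })
    cols = ["frame", "t_min", "cell_label", "area_um2", "major_um", "minor_um",
            "eccentricity_index", "alignment_deg", "x_um", "y_um", "zone", "degenerate"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Transverse cell metrics
# ---------------------------------------------------------------------------

def transverse_cell_metrics(
    source,
    config: KinematicConfig | None = None,
    pixel_size_zx: tuple[float, float] | None = None,
    midline_x: float | None = None,
    frames: list[int] | None = None,
) -> pd.DataFrame:
    """Long-axis length and angle to the parasagittal plane of transverse cells.

    ``source`` is either a ground-truth table (cells rasterised as filled
    ellipses at the stack calibration, then measured by moments — the same
    measurement path as segmented data) or a per-frame dict of label masks.
    Angles are measured against the parasagittal (vertical) plane and lie in
    [0, 90]. Returns frame, t_min, cell_id, long_axis_um, angle_deg, zone.
    """
    if isinstance(source, pd.DataFrame):
        if config is None:
            raise ValueError("config required when measuring from a truth table")
        return _metrics_from_truth(source, config, frames)
    if pixel_size_zx is None or midline_x is None:
        raise ValueError("pixel_size_zx and midline_x required for label-mask input")
    rows = []
    for frame, labels in source.items():
        for lab in range(1, int(labels.max()) + 1):
            region = labels == lab
            if not region.any():
                continue
            _, (cx, cz), mom = region_moments(region, pixel_size_zx)
            major, _, orient, degen = axis_metrics(mom)
            angle = float("nan") if degen else 90.0 - alignment_angle(orient, 0.0)
            rows.append((frame, lab, major, angle, assign_zone(cx, midline_x)))
    return pd.DataFrame(rows, columns=["frame", "cell_id", "long_axis_um", "angle_deg", "zone"])


def _metrics_from_truth(
    truth: pd.DataFrame, config: KinematicConfig, frames: list[int] | None
) -> pd.DataFrame:
    dz, _, dx = config.voxel_size
    mid = config.midline_x
    sel = truth if frames is None else truth[truth["frame"].isin(frames)]
    rows = []
    for _, c in sel.iterrows():
        mask, origin = _rasterise_ellipse(
            c["long_axis_um"] / 2.0, config.cell_width / 2.0, c["angle_deg"],
            np.sign(mid - c["x_um"]) or 1.0, dz, dx,
        )
        if not mask.any():
            continue
        # moments in the (z=row, x=col) raster => pixel_size (dz, dx)
        _, _, mom = region_moments(mask, (dz, dx))
        major, _, orient, degen = axis_metrics(mom)
        angle = float("nan") if degen else 90.0 - alignment_angle(orient, 0.0)
        rows.append((
            int(c["frame"]), float(c["t_min"]), int(c["cell_id"]),
            major, angle, assign_zone(c["x_um"], mid),
        ))
    return pd.DataFrame(
        rows, columns=["frame", "t_min", "cell_id", "long_axis_um", "angle_deg", "zone"]
    )


def _rasterise_ellipse(a_um, b_um, angle_deg, lean_sign, dz, dx):
    """Filled-ellipse raster on a (z=row, x=col) grid, axis tilted angle_deg
    from vertical leaning toward lean_sign."""
    th = np.deg2rad(angle_deg)
    ux, uz = lean_sign * np.sin(th), np.cos(th)
    half = a_um + max(dz, dx)
    zs = np.arange(-half, half + dz, dz)
    xs = np.arange(-half, half + dx, dx)
    X, Z = np.meshgrid(xs, zs)
    u = X * ux + Z * uz
    v = -X * uz + Z * ux
    mask = (u / a_um) ** 2 + (v / b_um) ** 2 <= 1.0
    return mask, (zs[0], xs[0])


# ---------------------------------------------------------------------------
# Area time series and internalisation events
# ---------------------------------------------------------------------------

def surface_area_timeseries(records: pd.DataFrame) -> pd.DataFrame:
    """Per-zone mean dorsal area vs time from linked per-cell records.

    ``records`` must carry track_id, frame, t_min, area_um2 and zone; each
    track's zone is frozen at its first appearance. Emits per frame and zone
    the mean area, SEM, n and the series normalised to its first frame.
    """
    from .profiles_stats import sem

    rec = records.copy()
    first = rec.sort_values("frame").groupby("track_id")["zone"].first()
    rec["zone0"] = rec["track_id"].map(first)
    rows = []
    for (frame, zone), grp in rec.groupby(["frame", "zone0"]):
        rows.append({
            "frame": frame,
            "t_min": grp["t_min"].iloc[0],
            "zone": zone,
            "mean_area_um2": grp["area_um2"].mean(),
            "sem_area_um2": sem(grp["area_um2"].to_numpy()),
            "n_cells": len(grp),
        })
    out = pd.DataFrame(rows).sort_values(["zone", "frame"]).reset_index(drop=True)
    for zone, grp in out.groupby("zone"):
        base = grp["mean_area_um2"].iloc[0]
        out.loc[grp.index, "normalised_area"] = grp["mean_area_um2"] / base if base > 0 else np.nan
    return out


@dataclass(frozen=True)
class InternalisationEvent:
    track_id: int
    event_time_min: float
    abs_x_um: float
    area_um2: float


def detect_internalisation_events(
    records: pd.DataFrame,
    midline_x: float,
    n_frames: int,
    area_floor_frac: float = 0.2,
    confirm_frames: int = 2,
) -> pd.DataFrame:
    """Detect cell internalisation events in linked dorsal-profile records.

    An event fires for a track whose area falls below ``area_floor_frac`` of
    its initial area and which then disappears for at least ``confirm_frames``
    consecutive frames before the movie ends (tracks lost at the very end are
    censored, not events). The event time is the first sub-floor frame; the
    recorded position is the track's last centroid distance to the midline.
    """
    rows = []
    for tid, grp in records.groupby("track_id"):
        grp = grp.sort_values("frame")
        a0 = grp["area_um2"].iloc[0]
        if a0 <= 0:
            continue
        sub = grp[grp["area_um2"] < area_floor_frac * a0]
        if sub.empty:
            continue
        last_frame = grp["frame"].max()
        if last_frame + confirm_frames >= n_frames:
            continue  # censored: no room to confirm disappearance
        first_sub = sub.iloc[0]
        rows.append({
            "track_id": tid,
            "event_time_min": first_sub["t_min"],
            "abs_x_um": abs(grp["x_um"].iloc[-1] - midline_x),
            "area_um2": first_sub["area_um2"],
        })
    return pd.DataFrame(rows, columns=["track_id", "event_time_min", "abs_x_um", "area_um2"])
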