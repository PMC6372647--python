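"""Reporter-channel intensity profiling and the study's statistics.

Profiles are reported along the two axes the biology cares about: the
mediolateral distribution of signal at the tissue surface (is myosin enriched
over the midline?) and the dorsoventral decay below the surface (is the signal
confined to the superficial cortex?). Each profile also emits a scalar
surrogate: the medial:lateral enrichment ratio (mean over 0–20 µm from the
midline divided by mean over 40–60 µm) and the depth steepness index (mean
over 0–5 µm below the surface divided by mean over 20–40 µm).

Group statistics follow the study: two-sided Mann-Whitney U (exact by full
enumeration for small samples without ties, normal approximation with tie and
continuity corrections otherwise) and SEM error bars.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import ImageStack, write_table


# ---------------------------------------------------------------------------
# ROI and background handling
# ---------------------------------------------------------------------------

def roi_mean_intensity(
    image: np.ndarray,
    center_um: tuple[float, float],
    pixel_size: tuple[float, float],
    roi_size: float = 3.0,
    dynamic_range: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean intensity and 256-bin histogram of a square ROI.

    ``center_um`` is (y, x) in µm; the ROI spans ``roi_size`` µm per side and
    must lie fully inside the image. The histogram covers ``dynamic_range``
    (default: the image's own min/max) rescaled to 256 gray levels.
    """
    dy, dx = pixel_size
    cy, cx = center_um
    hy, hx = roi_size / 2.0, roi_size / 2.0
    r0, r1 = int(round((cy - hy) / dy)), int(round((cy + hy) / dy))
    c0, c1 = int(round((cx - hx) / dx)), int(round((cx + hx) / dx))
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError("ROI out of image bounds")
    roi = image[r0:max(r1, r0 + 1), c0:max(c1, c0 + 1)].astype(np.float64)
    if dynamic_range is None:
        dynamic_range = (float(image.min()), float(image.max()))
    lo, hi = dynamic_range
    hist, _ = np.histogram(roi, bins=256, range=(lo, hi if hi > lo else lo + 1))
    return float(roi.mean()), hist


def subtract_background(values, background: float):
    """Subtract a membrane-free background level, clamping at zero."""
    arr = np.asarray(values, dtype=float)
    out = np.clip(arr - background, 0.0, None)
    if np.isscalar(values) or arr.ndim == 0:
        return float(out)
    return out


def surface_projection(
    stack_or_volume,
    slice_windows: list[tuple[int, int]],
) -> np.ndarray:
    """Average of maximum-intensity projections over given z-slice windows.

    Each window (lo, hi) is an inclusive slice-index range near the tissue
    surface; windows of 3-4 representative slices mirror the study's "true
    signal" rule. Raises when a window exceeds the stack depth.
    """
    vol = stack_or_volume.data if isinstance(stack_or_volume, ImageStack) else stack_or_volume
    if vol.ndim == 4:  # (t,z,y,x): caller passes one frame normally
        raise ValueError("surface_projection expects a single (z,y,x) volume")
    projections = []
    for lo, hi in slice_windows:
        if lo < 0 or hi >= vol.shape[0] or hi < lo:
            raise ValueError(f"slice window ({lo},{hi}) outside stack depth {vol.shape[0]}")
        projections.append(vol[lo : hi + 1].max(axis=0).astype(np.float64))
    return np.mean(projections, axis=0)


# ---------------------------------------------------------------------------
# Axis profiles
# ---------------------------------------------------------------------------

@dataclass
class IntensityProfile:
    axis: str                   # "mediolateral" | "dorsoventral"
    bin_centers_um: np.ndarray
    mean_intensity: np.ndarray
    n_pixels: np.ndarray
    background: float
    summary_ratio: float        # enrichment (ML) or steepness (DV)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "axis": self.axis,
            "bin_center_um": self.bin_centers_um,
            "mean_intensity": self.mean_intensity,
            "normalised_intensity": self.mean_intensity / self.mean_intensity.max()
            if np.nanmax(self.mean_intensity) > 0 else self.mean_intensity,
            "n_pixels": self.n_pixels,
        })


def ml_profile(
    surface_image: np.ndarray,
    pixel_dx: float,
    midline_x: float,
    bin_width: float = 5.0,
    max_dist: float = 60.0,
    background: float = 0.0,
) -> IntensityProfile:
    """Mediolateral surface intensity profile in |x − midline| bins.

    Averages over the image rows (AP extent) within each distance bin from 0
    to ``max_dist`` µm and emits the medial:lateral enrichment ratio
    mean(0-20)/mean(40-60). The image should be background-corrected; a
    residual ``background`` can be subtracted here.
    """
    img = subtract_background(surface_image.astype(np.float64), background)
    ncols = img.shape[-1]
    dist = np.abs(np.arange(ncols) * pixel_dx - midline_x)
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    flat = img.reshape(-1, ncols)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        cols = (dist >= lo) & (dist < hi)
        if cols.any():
            vals = flat[:, cols]
            means[i] = vals.mean()
            counts[i] = vals.size
    medial = _band_mean(flat, dist, 0.0, 20.0)
    lateral = _band_mean(flat, dist, 40.0, 60.0)
    ratio = medial / lateral if (lateral is not None and lateral > 0 and medial is not None) else np.nan
    return IntensityProfile("mediolateral", centers, means, counts, background, float(ratio))


def _band_mean(flat, dist, lo, hi):
    cols = (dist >= lo) & (dist < hi)
    if not cols.any():
        return None
    return float(flat[:, cols].mean())


def locate_surface(frame_zx: np.ndarray, dz: float, threshold_frac: float = 0.3) -> np.ndarray:
    """Per-column z (µm) of the dorsal tissue surface in a transverse frame.

    The surface is the first row exceeding ``threshold_frac`` of the column
    band's robust maximum; columns with no signal get NaN.
    """
    img = frame_zx.astype(np.float64)
    robust = np.percentile(img, 99)
    above = img > threshold_frac * robust
    has = above.any(axis=0)
    first = np.argmax(above, axis=0).astype(float)
    first[~has] = np.nan
    return first * dz


def dv_profile(
    frame_zx: np.ndarray,
    voxel_zx: tuple[float, float],
    surface_z_um: np.ndarray | None = None,
    bin_width: float = 2.5,
    depth_range: float = 40.0,
    background: float = 0.0,
    steep_bands: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 5.0), (20.0, 40.0)),
) -> IntensityProfile:
    """Depth-below-surface intensity profile of a transverse frame.

    Depth is measured per column from the located (or supplied) dorsal surface
    down to ``depth_range`` µm; the steepness index is the superficial band
    mean over the deep band mean (default 0-5 µm vs 20-40 µm).
    """
    dz, dx = voxel_zx
    img = subtract_background(frame_zx.astype(np.float64), background)
    if surface_z_um is None:
        surface_z_um = locate_surface(frame_zx, dz)
    if np.all(np.isnan(surface_z_um)):
        raise ValueError("dv_profile: tissue surface not located in any column")
    nrow = img.shape[0]
    zcol = np.arange(nrow)[:, None] * dz
    depth = zcol - surface_z_um[None, :]
    valid = np.isfinite(depth) & (depth >= 0) & (depth <= depth_range)
    edges = np.arange(0.0, depth_range + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = valid & (depth >= lo) & (depth < hi)
        if sel.any():
            means[i] = img[sel].mean()
            counts[i] = int(sel.sum())
    (s_lo, s_hi), (d_lo, d_hi) = steep_bands
    sup = valid & (depth >= s_lo) & (depth < s_hi)
    deep = valid & (depth >= d_lo) & (depth < d_hi)
    ratio = img[sup].mean() / img[deep].mean() if sup.any() and deep.any() and img[deep].mean() > 0 else np.nan
    return IntensityProfile("dorsoventral", centers, means, counts, background, float(ratio))


def surface_band_image(
    frame_zx: np.ndarray,
    voxel_zx: tuple[float, float],
    band_um: float = 5.0,
    surface_frame: np.ndarray | None = None,
) -> np.ndarray:
    """Mean intensity of the first ``band_um`` µm below the surface, per column.

    Produces a (1, x) "surface image" from a transverse frame, the transverse
    counterpart of a dorsal surface projection; the surface is located on
    ``surface_frame`` (e.g. the membrane channel) when given.
    """
    dz, dx = voxel_zx
    ref = frame_zx if surface_frame is None else surface_frame
    surf = locate_surface(ref, dz)
    nrow = frame_zx.shape[0]
    zcol = np.arange(nrow)[:, None] * dz
    depth = zcol - surf[None, :]
    sel = np.isfinite(depth) & (depth >= 0) & (depth < band_um)
    img = frame_zx.astype(np.float64)
    out = np.full(frame_zx.shape[1], np.nan)
    counts = sel.sum(axis=0)
    sums = np.where(sel, img, 0.0).sum(axis=0)
    good = counts > 0
    out[good] = sums[good] / counts[good]
    return out[None, :]


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str  # "exact" | "normal_approximation"


def mann_whitney(sample_a, sample_b, exact_limit: int = 12) -> StatResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The p-value is exact (full enumeration of all ``C(n1+n2, n1)`` group
    labelings) when ``n1 + n2 <= exact_limit`` and there are no ties, else a
    normal approximation with tie and continuity corrections is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney: both samples must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(combined).size < combined.size
    if n1 + n2 <= exact_limit and not has_ties:
        p = _exact_two_sided_p(ranks, n1, u1)
        return StatResult(float(u1), float(p), n1, n2, "exact")

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return StatResult(float(u1), 1.0, n1, n2, "normal_approximation")
    z = (abs(u1 - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * (1.0 - _norm_cdf(z)))
    return StatResult(float(u1), float(p), n1, n2, "normal_approximation")


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all group-A rank subsets."""
    n = len(ranks)
    n1n2 = n1 * (n - n1)
    u_low = min(u_obs, n1n2 - u_obs)
    count = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for subset in itertools.combinations(ranks, n1):
        u = sum(subset) - offset
        if u <= u_low + 1e-12 or u >= n1n2 - u_low - 1e-12:
            count += 1
        total += 1
    return min(1.0, count / total)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def sem(values) -> float:
    """Standard error of the mean (sample sd with n−1 denominator over √n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return float("nan")
    return float(arr.std(ddof=1) / math.sqrt(arr.size))


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def build_report(outputs: dict, out_dir: str | Path, manifest: dict | None = None) -> Path:
    """Write each stage output table to CSV plus a JSON run manifest.

    ``outputs`` maps table names (e.g. ``depth_series``, ``area_timeseries``,
    ``angle_summary``, ``speed_summary``, ``events``, ``ml_profile``,
    ``dv_profile``) to DataFrames; missing stages are listed as absent in the
    manifest and the report is still written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written, absent = [], []
    for name, table in outputs.items():
        if table is None:
            absent.append(name)
            continue
        if isinstance(table, IntensityProfile):
            table = table.to_frame()
        write_table(table, out_dir / f"{name}.csv")
        written.append(name)
    from . import __version__

    info = {
        "package": "keelquant",
        "version": __version__,
        "tables": sorted(written),
        "absent": sorted(absent),
    }
    if manifest:
        info.update(manifest)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    return path
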