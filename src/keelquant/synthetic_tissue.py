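"""Ground-truthed synthetic movies of a converging, internalising neural plate.

The generator prescribes cell kinematics (it is not a mechanical simulation)
and renders them in the three imaging modalities used to study zebrafish
neural-plate internalisation:

* a transverse (z, x) membrane/myosin/actin view of the deepening tissue,
* a dorsal tangential (y, x) membrane view of cell surface profiles under an
  EVL-like superficial layer,
* a 3D+t nuclei view of Gaussian blobs at cell centroids.

Every render is a deterministic function of the config (including its seed),
and ships with a per-cell per-frame ground-truth table so each downstream
stage can be validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter

from .io_core import ConfigurationError, ImageStack

# zone bounds (µm from the midline): medial < MEDIAL_HALFWIDTH,
# lateral in [MEDIAL_HALFWIDTH, LATERAL_MAX], outside beyond.
MEDIAL_HALFWIDTH = 20.0
LATERAL_MAX = 60.0


@dataclass(frozen=True)
class KinematicConfig:
    """Full parameterisation of one synthetic tissue movie.

    Lengths µm, times minutes, angles degrees. Rates noted per hour are
    fractional losses per hour: a constriction_rate of 0.5 means a cell's
    dorsal profile area is multiplied by (1 - 0.5) every 60 minutes.
    """

    preset_name: str = "custom"
    seed: int = 0

    # geometry
    n_cells: int = 100
    field_width: float = 120.0          # mediolateral extent; midline at centre
    ap_extent: float = 60.0             # anteroposterior extent
    initial_depth: float = 42.0         # midline tissue depth at t = 0
    final_depth: float = 138.0          # midline tissue depth at t = duration
    tissue_top: float = 5.0             # z of the dorsal tissue surface (transverse)
    depth_core_halfwidth: float = 15.0  # |x| within which the full depth applies
    depth_taper_halfwidth: float = 25.0  # taper width of deepening beyond the core

    # kinematics
    duration: float = 180.0
    frame_interval: float = 2.5
    convergence_speed: float = 0.25     # peak medial drift, µm/min
    anterior_drift_speed: float = 0.2   # pre-onset anterior drift, µm/min
    position_jitter_sd: float = 0.12    # per-step random-walk sd, µm
    internalisation_onset: float = 60.0
    internalisation_zone_halfwidth: float = 20.0
    constriction_rate: float = 0.5      # fractional dorsal-area loss per hour (zone-triggered)
    constriction_rate_sd: float = 0.06  # per-cell spread of the zone-triggered rate
    constriction_anisotropy: float = 1.6  # ML:AP linear shrink ratio (>= 1)
    ectopic_event_rate: float = 0.0     # random events / h / cell, any |x| <= 60
    ectopic_area_loss_per_hour: float = 0.95  # ectopic events constrict fast
    disappear_frac: float = 0.1         # area fraction at which a cell leaves the plane

    # transverse cell shapes
    cell_length_early: float = 14.0
    cell_length_late_medial: float = 34.0
    cell_length_late_lateral: float = 20.0
    cell_width: float = 7.0
    angle_early: float = 50.0
    angle_late_medial: float = 30.0
    angle_late_lateral: float = 80.0
    angle_jitter_sd: float = 4.0

    # dorsal profile areas
    cell_area_mean: float = 58.0        # µm², before field-fill rescaling
    cell_area_log_sd: float = 0.22
    dorsal_fill_frac: float = 0.80      # prescribed areas sum to this fraction of the field

    # channel rendering
    membrane_thickness: float = 1.4
    nucleus_sigma: float = 2.0
    myosin_ml_profile: str = "peaked"   # "peaked" | "flat"
    myosin_ml_width: float = 20.0
    myosin_ml_floor: float = 0.3
    myosin_dv_decay: float = 5.0
    actin_dv_decay: float = 40.0
    evl_thickness: float = 4.0          # dorsal view EVL layer
    surface_plane_offset: float = 6.0   # tessellation plane, µm below the EVL bottom
    background: float = 10.0
    noise_sd: float = 4.0

    # calibration
    voxel_size: tuple[float, float, float] = (1.05, 0.69, 0.69)
    dorsal_dz: float = 1.0              # finer z sampling for dorsal stacks

    def __post_init__(self) -> None:
        positive = [
            "n_cells", "field_width", "ap_extent", "initial_depth", "final_depth",
            "duration", "frame_interval", "internalisation_zone_halfwidth",
            "membrane_thickness", "nucleus_sigma", "myosin_dv_decay",
            "actin_dv_decay", "cell_width", "cell_area_mean", "dorsal_dz",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        nonneg = [
            "convergence_speed", "anterior_drift_speed", "constriction_rate",
            "ectopic_event_rate", "noise_sd", "background", "position_jitter_sd",
            "internalisation_onset",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.constriction_rate < 1:
            raise ConfigurationError("constriction_rate must be a fraction in [0, 1)")
        if self.constriction_anisotropy < 1:
            raise ConfigurationError("constriction_anisotropy must be >= 1")
        if self.final_depth < self.initial_depth:
            raise ConfigurationError("final_depth must be >= initial_depth")
        if self.myosin_ml_profile not in ("peaked", "flat"):
            raise ConfigurationError("myosin_ml_profile must be 'peaked' or 'flat'")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel_size entries must be > 0")

    # -- derived quantities --------------------------------------------------
    @property
    def midline_x(self) -> float:
        return self.field_width / 2.0

    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames()) * self.frame_interval

    def midline_depth_at(self, t) -> np.ndarray:
        """Prescribed midline depth (µm): flat before onset, then a monotone
        smoothstep from initial_depth to final_depth."""
        t = np.asarray(t, dtype=float)
        span = max(self.duration - self.internalisation_onset, 1e-9)
        u = np.clip((t - self.internalisation_onset) / span, 0.0, 1.0)
        s = u * u * (3.0 - 2.0 * u)
        return self.initial_depth + (self.final_depth - self.initial_depth) * s

    def depth_at(self, x_um, t) -> np.ndarray:
        """Tissue depth at mediolateral position x (µm from left edge)."""
        d = np.abs(np.asarray(x_um, dtype=float) - self.midline_x)
        u = np.clip((d - self.depth_core_halfwidth) / self.depth_taper_halfwidth, 0.0, 1.0)
        taper = 0.5 * (1.0 + np.cos(np.pi * u))
        dm = self.midline_depth_at(t)
        return self.initial_depth + (dm - self.initial_depth) * taper

    def myosin_ml_factor(self, x_um) -> np.ndarray:
        """Mediolateral myosin enrichment factor P(x) in [floor, 1]."""
        if self.myosin_ml_profile == "flat":
            return np.ones_like(np.asarray(x_um, dtype=float))
        d = np.asarray(x_um, dtype=float) - self.midline_x
        p0 = self.myosin_ml_floor
        return p0 + (1.0 - p0) * np.exp(-(d ** 2) / (2.0 * self.myosin_ml_width ** 2))


_PRESETS = {
    "wild_type": dict(
        preset_name="wild_type",
    ),
    "cdh2_deficient": dict(
        preset_name="cdh2_deficient",
        initial_depth=44.0,
        final_depth=85.0,
        convergence_speed=0.05,     # convergence is severely compromised
        anterior_drift_speed=0.05,
        constriction_rate=0.0,          # no coordinated medial constriction
        ectopic_event_rate=0.15,        # random events across the plate width
        myosin_ml_profile="flat",
    ),
    "myosin_inhibited": dict(
        preset_name="myosin_inhibited",
        final_depth=42.0,               # no deepening: trajectory stays flat
        constriction_rate=0.0,
        convergence_speed=0.05,
    ),
}


def make_preset(name: str, **overrides) -> KinematicConfig:
    """Return the kinematic config of a named experimental condition."""
    if name not in _PRESETS:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        )
    params = dict(_PRESETS[name])
    params.update(overrides)
    return KinematicConfig(**params)


def dorsal_run_config(config: KinematicConfig, duration: float = 60.0) -> KinematicConfig:
    """Variant of a preset for dorsal tangential movies.

    Dorsal surface-profile movies cover the constriction window itself, so the
    clock starts at internalisation onset (Fig-2-style 60-minute window).
    """
    return dataclasses.replace(config, duration=duration, internalisation_onset=0.0)


# ---------------------------------------------------------------------------
# Kinematic simulation
# ---------------------------------------------------------------------------

def _zone_of(dist: np.ndarray) -> np.ndarray:
    zone = np.where(dist < MEDIAL_HALFWIDTH, "medial",
                    np.where(dist <= LATERAL_MAX, "lateral", "outside"))
    return zone


def simulate_kinematics(config: KinematicConfig) -> pd.DataFrame:
    """Integrate the prescribed cell kinematics into a ground-truth table.

    One row per cell per frame with columns: frame, t_min, cell_id, x_um,
    y_um, z_um, dorsal_area_um2, long_axis_um, angle_deg (to the parasagittal
    plane), zone, internalised, event_time_min (NaN if none), constricting.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    times = config.times()
    mid = config.midline_x

    # jittered-grid initial placement
    nx = max(int(round(np.sqrt(n * config.field_width / config.ap_extent))), 1)
    ny = int(np.ceil(n / nx))
    gx, gy = np.meshgrid(
        (np.arange(nx) + 0.5) / nx * config.field_width,
        (np.arange(ny) + 0.5) / ny * config.ap_extent,
    )
    order = rng.permutation(nx * ny)[:n]
    x = gx.ravel()[order] + rng.normal(0, 0.25 * config.field_width / nx, n)
    y = gy.ravel()[order] + rng.normal(0, 0.25 * config.ap_extent / ny, n)
    x = np.clip(x, 1.0, config.field_width - 1.0)
    y = np.clip(y, 1.0, config.ap_extent - 1.0)

    # per-cell statics
    areas0 = rng.lognormal(np.log(config.cell_area_mean), config.cell_area_log_sd, n)
    areas0 *= config.dorsal_fill_frac * config.field_width * config.ap_extent / areas0.sum()
    depth_frac = rng.uniform(0.15, 0.85, n)
    angle_offset = rng.normal(0.0, config.angle_jitter_sd, n)
    length_jitter = rng.normal(1.0, 0.08, n)

    # per-cell constriction rates: cell-by-cell variability around the preset
    # rate (the mean cohort decay is unchanged: survival is linear in rate)
    if config.constriction_rate > 0 and config.constriction_rate_sd > 0:
        zone_rate = np.clip(
            rng.normal(config.constriction_rate, config.constriction_rate_sd, n),
            0.05, 0.95,
        )
    else:
        zone_rate = np.full(n, config.constriction_rate)

    # ectopic internalisation events: exponential waiting times (Poisson process)
    if config.ectopic_event_rate > 0:
        ectopic_start = config.internalisation_onset + rng.exponential(
            60.0 / config.ectopic_event_rate, n
        )
    else:
        ectopic_start = np.full(n, np.inf)

    constrict_start = np.full(n, np.inf)   # zone-triggered constriction
    frames = []
    dt = config.frame_interval
    span = max(config.duration - config.internalisation_onset, 1e-9)

    for k, t in enumerate(times):
        dist = np.abs(x - mid)

        # zone-triggered constriction: medial cells constrict from onset (or
        # from when they first enter the zone, if later)
        if config.constriction_rate > 0 and t >= config.internalisation_onset:
            entering = (dist < config.internalisation_zone_halfwidth) & ~np.isfinite(constrict_start)
            constrict_start[entering] = t

        # dorsal profile areas: exponential decay from each cell's trigger
        area = areas0.copy()
        zone_h = np.clip(t - constrict_start, 0.0, None) / 60.0
        if config.constriction_rate > 0:
            area *= (1.0 - zone_rate) ** zone_h
        ect_h = np.clip(t - ectopic_start, 0.0, None) / 60.0
        if config.ectopic_event_rate > 0:
            area *= (1.0 - config.ectopic_area_loss_per_hour) ** ect_h

        internalised = area < config.disappear_frac * areas0
        trigger = np.minimum(constrict_start, ectopic_start)
        event_time = np.full(n, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(
                ectopic_start < constrict_start,
                config.ectopic_area_loss_per_hour,
                zone_rate,
            )
            t_cross = np.where(
                (rate > 0) & np.isfinite(trigger),
                trigger + 60.0 * np.log(config.disappear_frac) / np.log1p(-rate),
                np.inf,
            )
        event_time[internalised] = t_cross[internalised]

        # transverse shape schedule: before onset round-ish leaning cells at
        # ~50 deg; after onset a position-dependent target (30 deg medial,
        # 80 deg lateral, narrow ramp at the zone boundary), linear in time
        u = np.clip((t - config.internalisation_onset) / span, 0.0, 1.0)
        ramp = np.clip((dist - (MEDIAL_HALFWIDTH - 3.0)) / 6.0, 0.0, 1.0)
        angle_target = config.angle_late_medial + ramp * (
            config.angle_late_lateral - config.angle_late_medial
        )
        angle = config.angle_early + u * (angle_target - config.angle_early) + angle_offset
        angle = np.clip(angle, 0.0, 90.0)
        length_target = config.cell_length_late_medial + ramp * (
            config.cell_length_late_lateral - config.cell_length_late_medial
        )
        length = (config.cell_length_early + u * (length_target - config.cell_length_early))
        length = length * length_jitter
        length = np.minimum(length, 0.9 * config.depth_at(x, t))

        # z position: cells ride the local deepening; internalised cells dive
        z = config.tissue_top + depth_frac * config.depth_at(x, t)

        frames.append(pd.DataFrame({
            "frame": k,
            "t_min": t,
            "cell_id": np.arange(n),
            "x_um": x.copy(),
            "y_um": y.copy(),
            "z_um": z,
            "dorsal_area_um2": area,
            "long_axis_um": length,
            "angle_deg": angle,
            "zone": _zone_of(dist),
            "internalised": internalised,
            "event_time_min": event_time,
            "constricting": np.isfinite(trigger) & (t >= trigger),
        }))

        if k == len(times) - 1:
            break

        # advance positions: medial drift with a sinusoidal time envelope
        # (accelerate then slow), tapering to zero at the midline
        envelope = np.sin(np.pi * np.clip(t / config.duration, 0, 1)) if config.duration > 0 else 0.0
        g = np.clip(dist / config.internalisation_zone_halfwidth, 0.0, 1.0)
        vx = -np.sign(x - mid) * config.convergence_speed * max(envelope, 0.15) * g
        vy = np.where(t < config.internalisation_onset, -config.anterior_drift_speed, 0.0)
        x = x + vx * dt + rng.normal(0, config.position_jitter_sd, n)
        y = y + vy * dt + rng.normal(0, config.position_jitter_sd, n)
        y = np.clip(y, 0.5, config.ap_extent - 0.5)
        x = np.clip(x, 0.5, config.field_width - 0.5)

    truth = pd.concat(frames, ignore_index=True)
    return truth


# ---------------------------------------------------------------------------
# Dorsal tangential render (capped additively-weighted Voronoi)
# ---------------------------------------------------------------------------

def _weighted_voronoi_frame(
    centers_px: np.ndarray,
    target_areas_px: np.ndarray,
    shape: tuple[int, int],
    weights: np.ndarray | None = None,
    max_iter: int = 25,
    tol: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterised additively-weighted Voronoi with a radius cap.

    A pixel belongs to cell i when ``d_i - w_i`` is minimal *and* non-positive,
    so cells are disks carved by hyperbolic bisectors and the tessellation
    need not fill the frame. Weights are adjusted iteratively until realised
    areas match the targets (median relative error < tol) or max_iter.

    Returns (labels (y,x) with 0 background and 1-based cell indices,
    realised areas in px, final weights).
    """
    ny, nx = shape
    m = len(centers_px)
    if m == 0:
        return np.zeros(shape, dtype=np.int32), np.zeros(0), np.zeros(0)
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float32)
    d = np.sqrt(
        (pts[:, 0, None] - centers_px[None, :, 0]) ** 2
        + (pts[:, 1, None] - centers_px[None, :, 1]) ** 2
    )  # (npix, m)
    if weights is None:
        weights = 1.05 * np.sqrt(target_areas_px / np.pi)
    weights = weights.astype(np.float32).copy()
    realised = np.zeros(m)
    labels_flat = np.zeros(pts.shape[0], dtype=np.int32)
    for _ in range(max_iter):
        f = d - weights[None, :]
        best = np.argmin(f, axis=1)
        fmin = f[np.arange(f.shape[0]), best]
        labels_flat = np.where(fmin <= 0.0, best + 1, 0)
        realised = np.bincount(labels_flat, minlength=m + 1)[1:].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.abs(realised - target_areas_px) / np.maximum(target_areas_px, 1.0)
        if np.median(rel) < tol and np.max(rel[target_areas_px > 4]) < 3 * tol:
            break
        weights += 0.9 * (np.sqrt(target_areas_px / np.pi) - np.sqrt(realised / np.pi))
        weights = np.maximum(weights, 0.0).astype(np.float32)
    return labels_flat.reshape(shape), realised, weights


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Pixels adjacent (4-connectivity) to a different label, incl. background."""
    b = np.zeros_like(labels, dtype=bool)
    b[:-1, :] |= labels[:-1, :] != labels[1:, :]
    b[1:, :] |= labels[1:, :] != labels[:-1, :]
    b[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    b[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    return b


def render_dorsal_view(
    truth: pd.DataFrame,
    config: KinematicConfig,
    return_truth_labels: bool = False,
):
    """Render the dorsal tangential membrane movie.

    The stack has an EVL-like bright layer on top (z in [0, evl_thickness]),
    a dim gap, and the cell-boundary plane at ``evl_thickness +
    surface_plane_offset``. Membrane intensity is painted on cell-cell and
    cell-interstitium boundaries; the interstitium left by internalised cells
    is membrane-bright (crowded membranes), cell interiors are dark.

    Returns an :class:`ImageStack`; with ``return_truth_labels=True`` also the
    per-frame ground-truth label stack (cell_id + 1 coded) and a DataFrame of
    realised polygon areas per cell per frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    dz = config.dorsal_dz
    _, dy, dx = config.voxel_size
    ny = int(round(config.ap_extent / dy))
    nx = int(round(config.field_width / dx))
    plane_z_um = config.evl_thickness + config.surface_plane_offset
    nz = int(round(plane_z_um / dz)) + 4
    n_frames = truth["frame"].max() + 1
    px_area = dy * dx

    membrane_int = 200.0
    interstitial_int = 170.0
    fill_int = 25.0

    # static EVL texture: large-scale smooth blobs
    evl = gaussian_filter(rng.normal(size=(ny, nx)), sigma=8.0 / dx)
    evl = 90.0 + 120.0 * (evl - evl.min()) / max(np.ptp(evl), 1e-9)
    evl_top_idx = int(np.floor(config.evl_thickness / dz))     # last EVL slice
    plane_idx = int(round(plane_z_um / dz))

    stack = np.zeros((n_frames, nz, ny, nx), dtype=np.float32)
    labels_out = np.zeros((n_frames, ny, nx), dtype=np.int32) if return_truth_labels else None
    realised_rows = []
    prev_weights: dict[int, float] = {}
    min_area_px = 2.0

    for k in range(n_frames):
        fr = truth[truth["frame"] == k]
        # internalised cells have left the imaging plane
        active = fr[~fr["internalised"] & (fr["dorsal_area_um2"] / px_area >= min_area_px)]
        ids = active["cell_id"].to_numpy()
        centers = np.stack(
            [active["y_um"].to_numpy() / dy, active["x_um"].to_numpy() / dx], axis=1
        )
        targets = active["dorsal_area_um2"].to_numpy() / px_area
        w0 = np.array([prev_weights.get(i, 1.05 * np.sqrt(a / np.pi))
                       for i, a in zip(ids, targets)], dtype=np.float32)
        labels, realised, weights = _weighted_voronoi_frame(
            centers, targets, (ny, nx), weights=w0,
            max_iter=30 if k == 0 else 12,
        )
        prev_weights = dict(zip(ids, weights))
        realised_rows.append(pd.DataFrame({
            "frame": k, "cell_id": ids, "realised_area_um2": realised * px_area,
            "target_area_um2": targets * px_area,
        }))

        # _boundary_mask marks both sides of each edge (2 px ≈ 2·dx µm wide);
        # dilate only if the configured membrane is thicker than that
        boundary = _boundary_mask(labels)
        extra = int(round((config.membrane_thickness / dx - 2.0) / 2.0))
        if extra > 0:
            boundary = binary_dilation(boundary, iterations=extra)
        plane = np.full((ny, nx), fill_int, dtype=np.float32)
        plane[labels == 0] = interstitial_int
        plane[boundary] = membrane_int

        vol = stack[k]
        vol[: evl_top_idx + 1] = evl[None]
        vol[plane_idx] = plane
        vol += config.background
        if labels_out is not None:
            lab = np.zeros((ny, nx), dtype=np.int32)
            remap = {j + 1: int(cid) + 1 for j, cid in enumerate(ids)}
            for j, cid in remap.items():
                lab[labels == j] = cid
            labels_out[k] = lab

    if config.noise_sd > 0:
        stack += rng.normal(0.0, config.noise_sd, stack.shape).astype(np.float32)
    np.clip(stack, 0, None, out=stack)
    out = ImageStack(
        np.round(stack).astype(np.uint16),
        voxel_size=(dz, dy, dx),
        frame_interval=config.frame_interval,
        channel_names=(),
    )
    if return_truth_labels:
        return out, labels_out, pd.concat(realised_rows, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Transverse render
# ---------------------------------------------------------------------------

def render_transverse_view(truth: pd.DataFrame, config: KinematicConfig) -> ImageStack:
    """Render the transverse (z, x) view with membrane, myosin, actin channels.

    The membrane channel carries a dim tissue fill (so the tissue mask is
    contiguous for depth measurement) plus bright cell-outline ellipses with
    the prescribed long axis and angle to the parasagittal plane. Myosin and
    actin decay exponentially below the dorsal surface with their configured
    length scales; the myosin mediolateral factor P(x) is peaked or flat.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    dz, _, dx = config.voxel_size
    nx = int(round(config.field_width / dx))
    nz = int(round((config.tissue_top + config.final_depth) / dz)) + 6
    n_frames = truth["frame"].max() + 1
    times = np.sort(truth["t_min"].unique())

    fill_int, membrane_int = 60.0, 200.0
    myo_amp, act_amp = 150.0, 150.0

    x_um = (np.arange(nx) * dx)[None, :]
    z_um = (np.arange(nz) * dz)[:, None]
    data = np.zeros((n_frames, nz, 1, nx, 3), dtype=np.float32)

    for k in range(n_frames):
        t = times[k]
        depth = config.depth_at(x_um[0], t)[None, :]
        tissue = (z_um >= config.tissue_top) & (z_um <= config.tissue_top + depth)
        below_surface = np.clip(z_um - config.tissue_top, 0.0, None)

        mem = np.full((nz, nx), 0.0, dtype=np.float32)
        mem[tissue] = fill_int

        fr = truth[truth["frame"] == k]
        for _, c in fr.iterrows():
            _draw_ellipse_outline(
                mem, c["x_um"], c["z_um"], c["long_axis_um"] / 2.0,
                config.cell_width / 2.0, c["angle_deg"],
                np.sign(config.midline_x - c["x_um"]) or 1.0,
                dx, dz, membrane_int, config.membrane_thickness,
            )
        mem[~tissue] = 0.0

        myo = (myo_amp * np.exp(-below_surface / config.myosin_dv_decay)
               * config.myosin_ml_factor(x_um[0])[None, :])
        act = act_amp * np.exp(-below_surface / config.actin_dv_decay)
        myo = np.where(tissue, myo, 0.0)
        act = np.where(tissue, act, 0.0)

        data[k, :, 0, :, 0] = mem
        data[k, :, 0, :, 1] = myo
        data[k, :, 0, :, 2] = act

    data += config.background
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, data.shape).astype(np.float32)
    np.clip(data, 0, None, out=data)
    return ImageStack(
        np.round(data).astype(np.uint16),
        voxel_size=(dz, config.voxel_size[1], dx),
        frame_interval=times[1] - times[0] if n_frames > 1 else config.frame_interval,
        channel_names=("membrane", "myosin", "actin"),
    )


def _draw_ellipse_outline(
    img: np.ndarray, cx_um: float, cz_um: float, a_um: float, b_um: float,
    angle_deg: float, lean_sign: float, dx: float, dz: float,
    intensity: float, thickness_um: float,
) -> None:
    """Paint an ellipse outline on a (z, x) image.

    ``angle_deg`` is the tilt of the major axis from the parasagittal
    (vertical) plane; the axis leans toward the midline (``lean_sign``).
    """
    th = np.deg2rad(angle_deg)
    # major-axis direction in (x, z)
    ux, uz = lean_sign * np.sin(th), np.cos(th)
    half = a_um + thickness_um
    x0 = max(int((cx_um - half) / dx), 0)
    x1 = min(int((cx_um + half) / dx) + 2, img.shape[1])
    z0 = max(int((cz_um - half) / dz), 0)
    z1 = min(int((cz_um + half) / dz) + 2, img.shape[0])
    if x0 >= x1 or z0 >= z1:
        return
    xs = np.arange(x0, x1) * dx - cx_um
    zs = np.arange(z0, z1) * dz - cz_um
    X, Z = np.meshgrid(xs, zs)
    u = X * ux + Z * uz
    v = -X * uz + Z * ux
    q = (u / a_um) ** 2 + (v / b_um) ** 2
    # band around q == 1, scaled so the painted band is ~thickness_um wide
    grad = 2.0 * np.sqrt((u / a_um**2) ** 2 + (v / b_um**2) ** 2)
    band = np.abs(q - 1.0) <= 0.5 * thickness_um * np.maximum(grad, 1e-6)
    region = img[z0:z1, x0:x1]
    region[band] = np.maximum(region[band], intensity)


# ---------------------------------------------------------------------------
# Nuclei render
# ---------------------------------------------------------------------------

def render_nuclei_view(truth: pd.DataFrame, config: KinematicConfig) -> ImageStack:
    """Render the 3D+t nuclei channel: isotropic Gaussian blobs at centroids."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    dz, dy, dx = config.voxel_size
    nx = int(round(config.field_width / dx))
    ny = int(round(config.ap_extent / dy))
    if len(truth) == 0:  # zero cells: pure background movie
        zmax = config.tissue_top + config.initial_depth
        n_frames = 1
    else:
        zmax = truth["z_um"].max() + 4 * config.nucleus_sigma
        n_frames = truth["frame"].max() + 1
    nz = int(np.ceil(zmax / dz)) + 1
    amp = 150.0
    sig = config.nucleus_sigma

    data = np.zeros((n_frames, nz, ny, nx), dtype=np.float32)
    for k in range(n_frames):
        fr = truth[truth["frame"] == k]
        vol = data[k]
        for _, c in fr.iterrows():
            _add_blob(vol, c["z_um"], c["y_um"], c["x_um"], sig, (dz, dy, dx), amp)

    data += config.background
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, data.shape).astype(np.float32)
    np.clip(data, 0, None, out=data)
    return ImageStack(
        np.round(data).astype(np.uint16),
        voxel_size=(dz, dy, dx),
        frame_interval=config.frame_interval,
        channel_names=(),
    )


def _add_blob(vol, z_um, y_um, x_um, sigma_um, voxel, amp) -> None:
    dz, dy, dx = voxel
    r = 4 * sigma_um
    z0 = max(int((z_um - r) / dz), 0); z1 = min(int((z_um + r) / dz) + 2, vol.shape[0])
    y0 = max(int((y_um - r) / dy), 0); y1 = min(int((y_um + r) / dy) + 2, vol.shape[1])
    x0 = max(int((x_um - r) / dx), 0); x1 = min(int((x_um + r) / dx) + 2, vol.shape[2])
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zs = (np.arange(z0, z1) * dz - z_um)[:, None, None]
    ys = (np.arange(y0, y1) * dy - y_um)[None, :, None]
    xs = (np.arange(x0, x1) * dx - x_um)[None, None, :]
    g = amp * np.exp(-(zs**2 + ys**2 + xs**2) / (2 * sigma_um**2))
    vol[z0:z1, y0:y1, x0:x1] += g
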