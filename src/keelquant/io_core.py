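"""Shared I/O plumbing: image stacks, tables, configs, coordinate conventions.

Conventions used throughout the package
---------------------------------------
* Axes: ``t`` (time), ``z`` (dorsoventral, ``z=0`` most dorsal), ``y``
  (anteroposterior), ``x`` (mediolateral, ``x=0`` at the left edge), optional
  trailing channel axis.
* Voxel indices are 0-based; physical positions are voxel *centers*, i.e.
  ``pos_um = index * voxel_size``.
* Lengths are µm, times are minutes, angles are degrees.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("keelquant")

#: acquisition calibration used when a file carries no metadata:
#: (dz, dy, dx) in µm and the frame interval in minutes.
DEFAULT_VOXEL_SIZE = (1.05, 0.69, 0.69)
DEFAULT_FRAME_INTERVAL = 2.5


class ConfigurationError(ValueError):
    """A config file or parameter set is invalid; the message names the key."""


@dataclass
class ImageStack:
    """A calibrated 4D/5D fluorescence stack indexed ``(t, z, y, x[, c])``."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"ImageStack data must be (t,z,y,x) or (t,z,y,x,c); got ndim={self.data.ndim}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("all voxel sizes must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.data.ndim == 5:
            if not self.channel_names:
                self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[-1]))
            if len(self.channel_names) != self.data.shape[-1]:
                raise ValueError("channel_names length must match the channel axis")
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")

    # -- convenience ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def axes(self) -> str:
        return "tzyx" if self.data.ndim == 4 else "tzyxc"

    def times(self) -> np.ndarray:
        """Frame acquisition times in minutes."""
        return np.arange(self.n_frames) * self.frame_interval

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a (t,z,y,x) array."""
        if self.data.ndim == 4:
            if self.channel_names and name not in self.channel_names:
                raise KeyError(name)
            return self.data
        return self.data[..., self.channel_names.index(name)]

    def extent_um(self) -> tuple[float, float, float]:
        """(z, y, x) physical extents in µm (voxel-center span)."""
        dz, dy, dx = self.voxel_size
        _, nz, ny, nx = self.data.shape[:4]
        return ((nz - 1) * dz, (ny - 1) * dy, (nx - 1) * dx)


@dataclass(frozen=True)
class PhysicalPoint:
    x: float
    y: float
    z: float
    t: float = 0.0


@dataclass(frozen=True)
class MidlineFrame:
    """Mediolateral midline position of one frame, in µm."""

    midline_x: float
    source: str  # "configured" | "estimated"
    score: float = float("nan")


def voxel_to_um(index: Sequence[float], voxel_size: Sequence[float]) -> np.ndarray:
    return np.asarray(index, dtype=float) * np.asarray(voxel_size, dtype=float)


def um_to_voxel(pos_um: Sequence[float], voxel_size: Sequence[float]) -> np.ndarray:
    return np.asarray(pos_um, dtype=float) / np.asarray(voxel_size, dtype=float)


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack to TIFF with the calibration embedded as shaped metadata."""
    path = Path(path)
    meta = {
        "axes": stack.axes,
        "voxel_size": list(stack.voxel_size),
        "frame_interval": stack.frame_interval,
        "channel_names": list(stack.channel_names),
    }
    tifffile.imwrite(path, stack.data, metadata=meta, photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    calibration_override: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` or a plain hyperstack.

    Missing calibration is filled from ``calibration_override`` or the default
    acquisition values, with a logged warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 3:  # single-timepoint volume: promote to one frame
        data = data[None]
    if data.ndim not in (4, 5):
        raise ConfigurationError(
            f"cannot infer axes for {data.ndim}-D data in {path}; supply a (t,z,y,x[,c]) stack"
        )
    voxel = meta.get("voxel_size")
    if voxel is None:
        voxel = calibration_override or DEFAULT_VOXEL_SIZE
        log.warning("%s has no voxel-size metadata; using %s µm", path.name, voxel)
    interval = meta.get("frame_interval")
    if interval is None:
        interval = frame_interval or DEFAULT_FRAME_INTERVAL
        log.warning("%s has no frame-interval metadata; using %s min", path.name, interval)
    channels = tuple(meta.get("channel_names", ()))
    return ImageStack(data, tuple(float(v) for v in voxel), float(interval), channels)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

_UNITS_COMMENT = "# units: lengths µm, times minutes, angles degrees, areas µm^2"


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a record table to CSV with a units comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_UNITS_COMMENT + "\n")
        records.to_csv(fh, index=False, float_format="%.8g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

def load_config(path_or_mapping) -> "object":
    """Load a :class:`~keelquant.synthetic_tissue.KinematicConfig` from YAML.

    The file is either ``{"preset": <name>, **overrides}`` or a full field
    mapping. Unknown keys are rejected and out-of-range values raise a
    :class:`ConfigurationError` naming the offending key.
    """
    from .synthetic_tissue import KinematicConfig, make_preset

    if isinstance(path_or_mapping, dict):
        raw = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path_or_mapping} is not a mapping")
    preset = raw.pop("preset", None)
    known = {f.name for f in dataclasses.fields(KinematicConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("voxel_size",):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    try:
        if preset is not None:
            return make_preset(preset, **raw)
        return KinematicConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_config(config, path: str | Path) -> Path:
    """Serialise a config dataclass to YAML (round-trips with load_config)."""
    path = Path(path)
    data = dataclasses.asdict(config)
    for key, val in data.items():
        if isinstance(val, tuple):
            data[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
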