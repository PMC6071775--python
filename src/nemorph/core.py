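"""Shared volume containers, physical-coordinate handling and I/O.

Axis order is (z, y, x) everywhere, matching slice-stack acquisition;
all physical quantities are in nanometres. TIFF stacks carry no
trustworthy 3D voxel size, so one must be supplied explicitly for TIFF
input; MRC headers win when present and nonzero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import mrc


@dataclass
class VoxelGrid:
    """A 3D intensity volume with per-axis physical voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar intensities, arbitrary dynamic range.
    voxel_size : (float, float, float)
        Physical voxel pitch (z, y, x) in nm; all components > 0.
    origin : (float, float, float)
        Physical position of voxel (0, 0, 0), in nm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid needs 3 axes, got {self.data.ndim}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_nm(self) -> tuple[float, float, float]:
        """Physical extent per axis: shape x voxel_size."""
        return tuple(s * v for s, v in zip(self.data.shape, self.voxel_size))

    def voxel_to_physical(self, idx) -> np.ndarray:
        """Map (z, y, x) voxel indices (may be fractional) to nm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)


@dataclass
class LabelVolume:
    """Integer label volume aligned to a :class:`VoxelGrid`.

    Label 0 is background; ``legend`` maps every nonzero label present
    to a structure name (``"NE"``, ``"vesicle"``, ...).
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    legend: dict[int, str] = field(default_factory=dict)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("LabelVolume needs 3 axes")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"legend missing entries for labels {sorted(missing)}")

    @property
    def shape(self):
        return self.labels.shape

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of all labels whose legend entry equals ``name``."""
        ids = [k for k, v in self.legend.items() if v == name]
        return np.isin(self.labels, ids)


class ResultTable:
    """A measurement table: one row per object, with per-column units."""

    def __init__(self, frame: pd.DataFrame, units: dict[str, str] | None = None):
        if frame.columns.duplicated().any():
            raise ValueError("duplicate column names")
        self.frame = frame
        self.units = dict(units or {})

    def write_csv(self, path) -> None:
        """Write CSV plus a ``<stem>.units.json`` sidecar of column units."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        sidecar = path.with_suffix(".units.json")
        sidecar.write_text(json.dumps(self.units, indent=1))

    @classmethod
    def read_csv(cls, path) -> "ResultTable":
        path = Path(path)
        frame = pd.read_csv(path)
        sidecar = path.with_suffix(".units.json")
        units = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(frame, units)


def read_volume(path, voxel_size_override: tuple[float, float, float] | None = None) -> VoxelGrid:
    """Read a multi-page TIFF or MRC stack into a :class:`VoxelGrid`.

    The MRC header's cell spacing supplies the voxel size when present
    and nonzero; otherwise ``voxel_size_override`` (nm, (z, y, x)) is
    required — a silent 1 nm assumption would corrupt every downstream
    physical measurement.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".mrc", ".rec", ".st", ".map"}:
        data, voxel = mrc.read_mrc(path)
        if voxel is None:
            voxel = voxel_size_override
    else:
        data = tifffile.imread(path)
        voxel = voxel_size_override
    data = np.asarray(data)
    if data.ndim == 2:
        raise ValueError(f"{path}: 2D image; a 3D stack is required")
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 axes, got {data.ndim}")
    if voxel is None:
        raise ValueError(
            f"{path}: no voxel size in file metadata and no override given; "
            "declare voxel_size_nm in the config"
        )
    return VoxelGrid(data, voxel)


def write_volume(path, grid: VoxelGrid) -> None:
    """Write a grid to TIFF or MRC by file extension."""
    path = Path(path)
    if path.suffix.lower() in {".mrc", ".rec", ".map"}:
        mrc.write_mrc(path, grid.data, grid.voxel_size)
    else:
        tifffile.imwrite(path, grid.data, photometric="minisblack")


def read_labels(path, voxel_size: tuple[float, float, float], legend: dict[int, str]) -> LabelVolume:
    grid = read_volume(path, voxel_size_override=voxel_size)
    return LabelVolume(grid.data.astype(np.int32), grid.voxel_size, legend)


def bin_volume(grid: VoxelGrid, factor: int) -> VoxelGrid:
    """Downscale by block-averaging ``factor``^3 blocks.

    Trailing partial blocks are dropped (not padded); voxel size is
    multiplied by ``factor``. ``factor=1`` is the identity.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("binning factor must be >= 1")
    if factor == 1:
        return VoxelGrid(grid.data.copy(), grid.voxel_size, grid.origin)
    nz, ny, nx = (s // factor for s in grid.shape)
    if min(nz, ny, nx) < 1:
        raise ValueError("volume smaller than binning factor on some axis")
    d = grid.data[: nz * factor, : ny * factor, : nx * factor].astype(np.float64)
    d = d.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    return VoxelGrid(d, tuple(v * factor for v in grid.voxel_size), grid.origin)


def to_uint8(grid: VoxelGrid, low_pct: float = 0.5, high_pct: float = 99.5) -> VoxelGrid:
    """Window to the [low_pct, high_pct] percentile range and map to 8 bit.

    Intensities are clipped to the percentile window, then linearly
    mapped to [0, 255]. A constant volume (zero range) maps to all
    zeros with a warning.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(grid.data, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("zero intensity range; mapping volume to all zeros")
        out = np.zeros(grid.shape, dtype=np.uint8)
    else:
        d = np.clip(grid.data.astype(np.float64), lo, hi)
        out = np.round((d - lo) / (hi - lo) * 255.0).astype(np.uint8)
    return VoxelGrid(out, grid.voxel_size, grid.origin)
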