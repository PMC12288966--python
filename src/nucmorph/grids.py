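"""Calibrated image containers and TIFF/YAML I/O.

All physical quantities in this package are micrometres (um). Arrays follow
the (z, y, x) axis convention for volumes and (y, x) for planes; the matching
``voxel_size`` tuple is stored in the *same* axis order as the array. User
facing entry points (CLI, sidecar files) accept the conventional (dx, dy, dz)
order and reverse it at the boundary.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["VoxelGrid", "LabelMap", "xyz_to_axis_order", "axis_to_xyz_order"]


def xyz_to_axis_order(voxel_xyz, ndim):
    """(dx, dy, dz) -> array-axis order ((dz, dy, dx) for 3D, (dy, dx) for 2D)."""
    v = tuple(float(x) for x in voxel_xyz)
    if len(v) == 1:
        v = v * ndim
    if len(v) < ndim:
        raise ValueError(f"need {ndim} voxel dimensions, got {v}")
    return tuple(reversed(v[:ndim]))


def axis_to_xyz_order(voxel_axis):
    return tuple(reversed(tuple(voxel_axis)))


@dataclass
class VoxelGrid:
    """A calibrated scalar image (3D stack or 2D plane).

    Parameters
    ----------
    data
        Intensity array, axes (z, y, x) or (y, x).
    voxel_size
        Physical voxel edge lengths in um, in the same axis order as ``data``.
    bit_depth
        8 or 16 for integer acquisitions, None for unconstrained float data
        (e.g. smoothed copies or simulated membrane channels).
    """

    data: np.ndarray
    voxel_size: tuple
    bit_depth: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError("VoxelGrid supports 2D and 3D arrays only")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.data.ndim:
            raise ValueError("voxel_size length must match array dimensionality")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("all voxel dimensions must be > 0")
        if self.bit_depth is not None:
            if self.bit_depth not in (8, 16):
                raise ValueError("bit_depth must be 8, 16 or None")
            lim = 2**self.bit_depth - 1
            if self.data.size and (self.data.min() < 0 or self.data.max() > lim):
                raise ValueError(f"intensities outside [0, {lim}] for {self.bit_depth}-bit grid")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self):
        return self.data.shape

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 3

    @property
    def voxel_volume(self) -> float:
        """Volume (um^3) of one voxel in 3D, area (um^2) of one pixel in 2D."""
        return float(np.prod(self.voxel_size))

    @property
    def extent(self):
        """Physical extent in um, array-axis order."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def copy_with(self, data, bit_depth="same") -> "VoxelGrid":
        bd = self.bit_depth if bit_depth == "same" else bit_depth
        return VoxelGrid(data, self.voxel_size, bd)

    def save(self, path) -> Path:
        """Write a (multi-page) TIFF plus a YAML calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.data)
        sidecar = path.with_suffix(path.suffix + ".yaml")
        meta = {
            "voxel_size_um_xyz": list(axis_to_xyz_order(self.voxel_size)),
            "axes": "zyx" if self.is_3d else "yx",
            "bit_depth": self.bit_depth,
        }
        sidecar.write_text(yaml.safe_dump(meta))
        return path

    @classmethod
    def load(cls, path, voxel_size_xyz=None) -> "VoxelGrid":
        """Read a TIFF; calibration from the YAML sidecar unless given explicitly."""
        path = Path(path)
        data = tifffile.imread(path)
        bit_depth = None
        if voxel_size_xyz is None:
            sidecar = path.with_suffix(path.suffix + ".yaml")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"{path}: no voxel calibration given and sidecar {sidecar.name} missing"
                )
            meta = yaml.safe_load(sidecar.read_text())
            voxel_size_xyz = meta["voxel_size_um_xyz"]
            bit_depth = meta.get("bit_depth")
        elif data.dtype == np.uint8:
            bit_depth = 8
        elif data.dtype == np.uint16:
            bit_depth = 16
        return cls(data, xyz_to_axis_order(voxel_size_xyz, data.ndim), bit_depth)

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(repr(self.voxel_size).encode())
        return h.hexdigest()


@dataclass
class LabelMap:
    """Integer-labelled segmentation on a calibrated lattice.

    0 is background; after filtering, labels are contiguous from 1. The
    ``provenance`` dict records every parameter that produced the map
    (threshold value, connectivity, filter settings, removal counts).
    """

    labels: np.ndarray
    voxel_size: tuple
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.labels.ndim:
            raise ValueError("voxel_size length must match array dimensionality")

    @property
    def ndim(self) -> int:
        return self.labels.ndim

    @property
    def shape(self):
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def ids(self):
        out = np.unique(self.labels)
        return out[out > 0]
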