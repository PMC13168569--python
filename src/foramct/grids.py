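"""Calibrated 3D image containers.

Volumes are stored slice-major as ``(z, y, x)`` arrays while the voxel
spacing is carried in user-facing Cartesian order ``(dx, dy, dz)`` in
micrometres per voxel.  The centre of voxel index ``(k, j, i)`` sits at the
physical point ``(i*dx, j*dy, k*dz)`` µm, i.e. voxel ``(0, 0, 0)`` is
centred on the origin.  All downstream geometry (distance transforms,
centroids, thickness) is expressed in µm using this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple

import numpy as np

Spacing = Tuple[float, float, float]


def _check_geometry(data: np.ndarray, spacing: Spacing, name: str) -> None:
    if not isinstance(data, np.ndarray) or data.ndim != 3:
        raise ValueError("volume data must be a 3D array (z, y, x)")
    if any(s < 1 for s in data.shape):
        raise ValueError("every axis must have extent >= 1")
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be three positive values (dx, dy, dz) in um")
    if not name:
        raise ValueError("name must be non-empty")


@dataclass
class VoxelGrid:
    """A calibrated greyscale volume (e.g. the post-cleanup ``Raw`` image)."""

    data: np.ndarray
    spacing: Spacing
    name: str = "Raw"

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        _check_geometry(self.data, self.spacing, self.name)

    @property
    def sampling(self) -> Tuple[float, float, float]:
        """Spacing reordered to array axis order ``(dz, dy, dx)``."""
        dx, dy, dz = self.spacing
        return (dz, dy, dx)

    @property
    def voxel_volume_um3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class BinaryMask:
    """A boolean volume sharing the calibration of its parent grid."""

    data: np.ndarray
    spacing: Spacing
    name: str = "Mask"

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("binary mask must be strictly two-valued")
            self.data = self.data.astype(bool)
        _check_geometry(self.data, self.spacing, self.name)

    sampling = VoxelGrid.sampling
    voxel_volume_um3 = VoxelGrid.voxel_volume_um3

    @property
    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelMap:
    """Non-negative integer labels; 0 is background, objects are 1..K."""

    data: np.ndarray
    spacing: Spacing
    name: str = "Labels"

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must hold integers")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be >= 0")
        _check_geometry(self.data, self.spacing, self.name)

    sampling = VoxelGrid.sampling
    voxel_volume_um3 = VoxelGrid.voxel_volume_um3

    @property
    def n_labels(self) -> int:
        return int(self.data.max())


@dataclass
class DistanceGrid:
    """Per-voxel Euclidean distances (µm) measured within one phase.

    ``domain`` records which phase the distances live on: voxels of the
    opposite phase are exactly zero.  Thickness maps reuse this container
    (thickness is also a non-negative µm field that is zero off-phase).
    """

    data: np.ndarray
    spacing: Spacing
    domain: Literal["foreground", "background"] = "foreground"
    name: str = "DistanceMap"

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.domain not in ("foreground", "background"):
            raise ValueError("domain must be 'foreground' or 'background'")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("distances must be >= 0")
        _check_geometry(self.data, self.spacing, self.name)

    sampling = VoxelGrid.sampling
    voxel_volume_um3 = VoxelGrid.voxel_volume_um3
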