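"""Infill removal, noise suppression and primary calcite segmentation.

Chambers of fossil tests are frequently occupied by granular sediment
infill whose greyscale overlaps neither background nor calcite; an
inclusive intensity band selects it and image arithmetic zeroes it out
before segmentation.  The calcite skeleton is then obtained by a 3D
Gaussian blur (sigma expressed in µm, converted per-axis to voxels),
an inclusive band threshold, and a keep-largest-region cleanup that
discards debris.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .grids import BinaryMask, VoxelGrid

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ThresholdRange:
    """Inclusive greyscale band [lo, hi]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"threshold lo ({self.lo}) must be <= hi ({self.hi})")


def connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndi.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def threshold_range(grid: VoxelGrid, rng: ThresholdRange, name: str = "Thresholded") -> BinaryMask:
    """Voxels with lo <= intensity <= hi (both inclusive)."""
    data = (grid.data >= rng.lo) & (grid.data <= rng.hi)
    return BinaryMask(data=data, spacing=grid.spacing, name=name)


def make_infill_mask(raw: VoxelGrid, rng: ThresholdRange) -> BinaryMask:
    """Band-threshold the raw volume to select sediment infill."""
    return threshold_range(raw, rng, name="Infill")


def remove_infill(raw: VoxelGrid, infill: BinaryMask) -> VoxelGrid:
    """Zero out infill voxels, yielding the cleaned ``Raw`` volume."""
    if raw.data.shape != infill.data.shape:
        raise ValueError("raw volume and infill mask shapes differ")
    data = raw.data.copy()
    data[infill.data] = 0
    return VoxelGrid(data=data, spacing=raw.spacing, name="Raw")


def gaussian_smooth_3d(grid: VoxelGrid, sigma_um: float) -> VoxelGrid:
    """Isotropic physical smoothing: per-axis sigma = sigma_um / spacing."""
    if sigma_um < 0:
        raise ValueError("sigma_um must be >= 0")
    dx, dy, dz = grid.spacing
    sigma_vox = (sigma_um / dz, sigma_um / dy, sigma_um / dx)
    data = ndi.gaussian_filter(grid.data.astype(np.float64), sigma=sigma_vox, mode="reflect")
    return VoxelGrid(data=data, spacing=grid.spacing, name=grid.name)


def keep_largest_region(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Retain only the largest connected component.

    Ties are broken deterministically in favour of the component whose
    first voxel appears earliest in raster order (labelling order).
    """
    structure = connectivity_structure(connectivity)
    labels, n = ndi.label(mask.data, structure=structure)
    if n == 0:
        raise ValueError("no foreground object")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))  # argmax returns the first (lowest label) on ties
    return BinaryMask(data=labels == keep, spacing=mask.spacing, name=mask.name)


def auto_threshold(grid: VoxelGrid) -> ThresholdRange:
    """Two-class Otsu split; the band runs from the split to the data maximum."""
    data = grid.data
    if np.ptp(data) == 0:
        raise ValueError("cannot auto-threshold a constant volume")
    lo = float(threshold_otsu(np.asarray(data)))
    return ThresholdRange(lo=lo, hi=float(data.max()))
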