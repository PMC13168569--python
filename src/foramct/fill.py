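"""Filled-test construction: morphological closing and EDT-based sealing.

The filled test (``FilledMask``) is the complete outer morphology with all
chambers solid.  For well-closed tests a morphological closing (dilate,
fill 3D holes, erode) suffices.  Tests with open apertures leak: their
chambers stay connected to the outside and hole filling cannot seal them.
For those, a two-stage Euclidean-distance procedure first grows the
calcite by a distance threshold ``t1`` (sealing apertures narrower than
``2*t1``), hole-fills, then trims the added rind back by a second distance
threshold ``t2`` so the outer surface is not artificially inflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball

from .grids import BinaryMask, DistanceGrid


def edt(mask: BinaryMask, domain: str = "foreground") -> DistanceGrid:
    """Anisotropy-aware 3D Euclidean distance transform in µm.

    ``domain="foreground"``: each foreground voxel's distance to the
    nearest background voxel centre; background voxels are 0.
    ``domain="background"`` is the symmetric case.  Array borders are
    padded with one layer of the opposite phase, so a mask that is
    entirely one phase still yields finite distances (measured against
    the virtual border).
    """
    if domain not in ("foreground", "background"):
        raise ValueError("domain must be 'foreground' or 'background'")
    phase = mask.data if domain == "foreground" else ~mask.data
    padded = np.pad(phase, 1, constant_values=False)
    dist = ndi.distance_transform_edt(padded, sampling=mask.sampling)
    return DistanceGrid(
        data=dist[1:-1, 1:-1, 1:-1],
        spacing=mask.spacing,
        domain=domain,
        name="DistanceMap",
    )


def fill_holes(data: np.ndarray) -> np.ndarray:
    """Fill background components not 6-connected to the array border."""
    return ndi.binary_fill_holes(data)


def close_fill(skeleton: BinaryMask, radius_vox: int) -> BinaryMask:
    """Dilate by a ball, fill 3D holes, erode by the same ball.

    The result is forced to be a superset of the skeleton (closing is
    extensive in the interior; the explicit union guards the array
    border, where erosion would otherwise bite into the input).
    """
    if radius_vox < 0:
        raise ValueError("radius_vox must be >= 0")
    data = skeleton.data
    if radius_vox > 0:
        selem = ball(radius_vox)
        data = ndi.binary_dilation(data, structure=selem)
        data = fill_holes(data)
        data = ndi.binary_erosion(data, structure=selem)
    else:
        data = fill_holes(data)
    data = data | skeleton.data
    return BinaryMask(data=data, spacing=skeleton.spacing, name="FilledMask")


@dataclass
class FilledReport:
    is_filled: bool
    hole_voxels: int = 0
    unfilled_aperture_count: int = 0
    aperture_voxels: int = 0


def is_filled(
    filled: BinaryMask,
    skeleton: BinaryMask,
    probe_radius_vox: int = 4,
    min_cavity_vox: int = 27,
) -> FilledReport:
    """Headless surrogate for the visual "is the test completely filled?" check.

    Two failure modes are probed: (a) enclosed holes that survived the
    closing (hole filling would change the mask), and (b) chambers still
    open to the outside through an aperture.  Open chambers are detected
    by re-running the dilate/fill-holes/erode sequence with a generous
    probe radius: a cavity that only that seals was reachable from the
    border.  Surface concavities (e.g. the crease between two chamber
    bulges) also appear in that difference, so a candidate only counts as
    an unfilled chamber if it is thicker than the probe ball itself — a
    chamber-scale void rather than a rolled-over crease.  Apertures wider
    than ``2*probe_radius_vox`` voxels evade the probe; the
    distance-based sealing stage handles those.
    """
    if filled.data.shape != skeleton.data.shape:
        raise ValueError("filled and skeleton shapes differ")
    holes = fill_holes(filled.data) & ~filled.data
    hole_voxels = int(holes.sum())

    probed = close_fill(filled, probe_radius_vox).data
    extra = probed & ~fill_holes(filled.data)
    labels, n = ndi.label(extra)  # 6-connected cavity candidates
    aperture_count = 0
    aperture_voxels = 0
    if n:
        depth = ndi.distance_transform_edt(extra, sampling=filled.sampling)
        max_depth = ndi.maximum(depth, labels, index=np.arange(1, n + 1))
        sizes = np.bincount(labels.ravel())[1:]
        probe_um = probe_radius_vox * min(filled.spacing)
        cavity = (sizes >= min_cavity_vox) & (np.atleast_1d(max_depth) > probe_um)
        aperture_count = int(cavity.sum())
        aperture_voxels = int(sizes[cavity].sum())
    return FilledReport(
        is_filled=(hole_voxels == 0 and aperture_count == 0),
        hole_voxels=hole_voxels,
        unfilled_aperture_count=aperture_count,
        aperture_voxels=aperture_voxels,
    )


def edt_seal(skeleton: BinaryMask, t1_um: float, t2_um: float) -> BinaryMask:
    """Two-stage distance-based sealing of a test with open apertures.

    Stage 1 unions the skeleton with all background within ``t1_um`` of it
    (a distance-threshold dilation that seals apertures narrower than
    ``2*t1_um``) and hole-fills.  Stage 2 keeps the voxels of that sealed
    solid at depth >= ``t2_um`` from its surface, unions the original
    skeleton back in, and hole-fills again, trimming the added rind so the
    outer test size is not inflated.  The result is guaranteed to contain
    the skeleton and to stay inside the hole-filled ``t1`` envelope.
    """
    if t1_um < 0 or t2_um < 0:
        raise ValueError("seal thresholds must be >= 0")
    # distance of background to the skeleton, with everything beyond the
    # array border treated as background (no virtual foreground, or the
    # dilation band would hug the border and hole filling would flood)
    bg = ndi.distance_transform_edt(~skeleton.data, sampling=skeleton.sampling)
    sealed = skeleton.data | (bg <= t1_um)
    sealed = fill_holes(sealed)
    envelope = sealed

    stage1 = BinaryMask(data=sealed, spacing=skeleton.spacing, name="Sealed")
    depth = edt(stage1, domain="foreground").data
    # depth is measured to the nearest background *centre*, so a surface
    # voxel of the original solid sits at depth t1 + one pitch; offsetting
    # t2 by one pitch makes seal-then-trim the identity on flat interfaces
    offset = min(skeleton.spacing) if t2_um > 0 else 0.0
    trimmed = (sealed & (depth >= t2_um + offset - 1e-9)) | skeleton.data
    trimmed = fill_holes(trimmed)

    if (skeleton.data & ~trimmed).any():
        raise AssertionError("sealed mask lost skeleton voxels")
    if (trimmed & ~envelope).any():
        raise AssertionError("sealed mask spilled beyond the t1 envelope")
    return BinaryMask(data=trimmed, spacing=skeleton.spacing, name="FilledMask")
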