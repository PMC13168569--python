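"""Independent brute-force oracles for small grids.

These deliberately avoid the algorithms used by the package: distances by
exhaustive all-pairs minimisation, components by explicit BFS flood fill,
thickness by literal sphere fitting, statistics by per-label Python
accumulation.  They are only tractable on tiny volumes and exist to pin
the fast implementations down.
"""

from collections import deque
from itertools import product

import numpy as np

_OFFSETS = {
    6: [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1],
    18: [o for o in product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, o)) <= 2],
    26: [o for o in product((-1, 0, 1), repeat=3) if any(o)],
}


def brute_edt(mask: np.ndarray, spacing_xyz, domain: str = "foreground") -> np.ndarray:
    """Exhaustive nearest-opposite-voxel distances (µm), border = opposite phase."""
    dx, dy, dz = spacing_xyz
    scale = np.array([dz, dy, dx], dtype=float)
    phase = mask if domain == "foreground" else ~mask
    padded = np.pad(phase, 1, constant_values=False)
    measured = np.argwhere(padded) * scale
    opposite = np.argwhere(~padded) * scale
    out = np.zeros(padded.shape)
    if measured.size and opposite.size:
        diff = measured[:, None, :] - opposite[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2)).min(axis=1)
        out[tuple(np.argwhere(padded).T)] = dist
    return out[1:-1, 1:-1, 1:-1]


def flood_fill_label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected components by BFS, labelled in raster order of first voxel."""
    offsets = _OFFSETS[connectivity]
    labels = np.zeros(mask.shape, dtype=np.int32)
    next_label = 0
    for start in np.ndindex(mask.shape):
        if not mask[start] or labels[start]:
            continue
        next_label += 1
        queue = deque([start])
        labels[start] = next_label
        while queue:
            z, y, x = queue.popleft()
            for oz, oy, ox in offsets:
                nz, ny, nx = z + oz, y + oy, x + ox
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not labels[nz, ny, nx]
                ):
                    labels[nz, ny, nx] = next_label
                    queue.append((nz, ny, nx))
    return labels


def brute_edge_mask(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 background 6-neighbour (border = background)."""
    edge = np.zeros(mask.shape, dtype=bool)
    for z, y, x in np.argwhere(mask):
        for oz, oy, ox in _OFFSETS[6]:
            nz, ny, nx = z + oz, y + oy, x + ox
            if not (
                0 <= nz < mask.shape[0]
                and 0 <= ny < mask.shape[1]
                and 0 <= nx < mask.shape[2]
            ) or not mask[nz, ny, nx]:
                edge[z, y, x] = True
                break
    return edge


def brute_local_thickness(mask: np.ndarray, spacing_xyz) -> np.ndarray:
    """Literal sphere fitting: th(x) = max{2 r(y) : |x - y| <= r(y)}."""
    dx, dy, dz = spacing_xyz
    scale = np.array([dz, dy, dx], dtype=float)
    radii = brute_edt(mask, spacing_xyz, "foreground")
    pts = np.argwhere(mask)
    coords = pts * scale
    r = radii[tuple(pts.T)]
    th = np.zeros(len(pts))
    for c, rad in zip(coords, r):
        covered = np.sqrt(((coords - c) ** 2).sum(axis=1)) <= rad + 1e-9
        th[covered] = np.maximum(th[covered], 2 * rad)
    out = np.zeros(mask.shape)
    out[tuple(pts.T)] = th
    return out


def brute_label_stats(labels: np.ndarray, signal: np.ndarray, spacing_xyz):
    """Per-label (count, volume, centroid_xyz_um, mean intensity) by iteration."""
    dx, dy, dz = spacing_xyz
    stats = {}
    for lbl in np.unique(labels):
        if lbl == 0:
            continue
        sel = labels == lbl
        zz, yy, xx = np.nonzero(sel)
        n = len(zz)
        stats[int(lbl)] = {
            "voxels": n,
            "volume_um3": n * dx * dy * dz,
            "centroid_um": (xx.mean() * dx, yy.mean() * dy, zz.mean() * dz),
            "mean_intensity": float(signal[sel].mean()),
        }
    return stats


def digitized_ball(radius_vox: int, pad: int = 2) -> np.ndarray:
    """Solid digital ball: lattice points with |v| <= r from the centre."""
    n = 2 * (radius_vox + pad) + 1
    c = radius_vox + pad
    zz, yy, xx = np.indices((n, n, n))
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


def hollow_ball(outer_vox: int, wall_vox: int, pad: int = 2) -> np.ndarray:
    """Spherical shell of the given outer radius and wall thickness."""
    n = 2 * (outer_vox + pad) + 1
    c = outer_vox + pad
    zz, yy, xx = np.indices((n, n, n))
    d2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
    return (d2 <= outer_vox**2) & (d2 > (outer_vox - wall_vox) ** 2)
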