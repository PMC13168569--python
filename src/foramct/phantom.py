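"""Synthetic foraminifera phantoms with exact voxel-level ground truth.

A phantom emulates the structures and nuisance factors seen in real µCT
scans of foraminifera: a spiral sequence of hollow calcite chambers whose
radii grow geometrically, shared septal walls between consecutive
chambers, optional inter-chamber apertures, random septal breaches
(dissolution), granular sediment infill of configurable density, and
greyscale contrast plus Gaussian noise.  The clean pre-noise geometry is
recorded as ground truth (chamber labels, wall/septum masks, volumes,
centroids, porosity), so every pipeline stage can be scored against an
exact reference without any external data.

Not emulated: beam hardening, ring artefacts, partial-volume blur from
the scanner PSF, or intra-wall micro-pores; phantom interfaces are
therefore one voxel sharp where real scans are gradual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .grids import BinaryMask, LabelMap, Spacing, VoxelGrid


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, degradation and imaging parameters of one phantom.

    Defaults describe a well-preserved benthic-like specimen at unit
    voxel pitch: five chambers growing by 20% in radius per chamber,
    6 µm calcite walls, sealed apertures, no dissolution, no infill,
    strong calcite/background contrast and no noise.
    """

    n_chambers: int = 5
    r0_um: float = 12.0
    growth_ratio: float = 1.2
    wall_um: float = 6.0
    aperture_um: float = 0.0
    septum_breach_frac: float = 0.0
    spiral: Tuple[float, float] = (6.0, 0.8)  # (z translation µm, rotation rad) per chamber
    infill_frac: float = 0.0
    intensities: Tuple[float, float, float] = (2000.0, 52000.0, 30000.0)  # bg, calcite, infill
    noise_sd: float = 0.0
    spacing: Spacing = (1.0, 1.0, 1.0)
    rng_seed: int = 0
    max_extent_vox: int = 420
    infill_grain_radius_vox: Tuple[int, int] = (1, 4)  # fine..coarse grains

    def __post_init__(self) -> None:
        if self.n_chambers < 1:
            raise ValueError("n_chambers must be >= 1")
        if self.wall_um <= 0:
            raise ValueError("wall_um must be > 0")
        if self.growth_ratio < 1:
            raise ValueError("growth_ratio must be >= 1")
        if not (0 <= self.aperture_um < self.r0_um):
            raise ValueError("aperture_um must lie in [0, r0_um)")
        if not (0 <= self.septum_breach_frac < 1):
            raise ValueError("septum_breach_frac must lie in [0, 1)")
        if not (0 <= self.infill_frac <= 1):
            raise ValueError("infill_frac must lie in [0, 1]")
        bg, calcite, infill = self.intensities
        if self.infill_frac > 0 and infill == calcite:
            raise ValueError("infill intensity must differ from calcite when infill present")


@dataclass
class PhantomTruth:
    """Exact pre-noise geometry of a generated phantom."""

    chamber_labels: LabelMap
    wall_mask: BinaryMask       # outer calcite (calcite minus septa)
    septum_mask: BinaryMask     # shared walls between consecutive chambers
    infill_mask: BinaryMask
    chamber_volumes_um3: List[float]
    chamber_centroids_um: List[Tuple[float, float, float]]
    wall_thickness_um: float
    porosity_pct: float
    rng_seed: int

    @property
    def calcite_mask(self) -> np.ndarray:
        """Full calcite phase: outer wall plus septa."""
        return self.wall_mask.data | self.septum_mask.data


def _chamber_layout(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Chamber centres (µm, xyz) and radii along the spiral.

    Consecutive centres are separated by r_k + r_{k+1} + wall so cavities
    stay exactly one septum apart; the direction turns by the rotation
    step around z and climbs by the translation step.
    """
    radii = spec.r0_um * spec.growth_ratio ** np.arange(spec.n_chambers)
    trans, rot = spec.spiral
    centres = np.zeros((spec.n_chambers, 3))
    for k in range(spec.n_chambers - 1):
        d = radii[k] + radii[k + 1] + spec.wall_um
        dz = min(abs(trans), 0.9 * d) * np.sign(trans) if trans else 0.0
        d_xy = np.sqrt(d**2 - dz**2)
        phi = k * rot
        centres[k + 1] = centres[k] + (d_xy * np.cos(phi), d_xy * np.sin(phi), dz)
    return centres, radii


def generate_phantom(spec: PhantomSpec) -> Tuple[VoxelGrid, PhantomTruth]:
    """Build the greyscale phantom volume and its ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    centres, radii = _chamber_layout(spec)
    dx, dy, dz = spec.spacing
    margin = 5  # voxels of clearance around the outermost shell

    outer = radii + spec.wall_um
    lo = (centres - outer[:, None]).min(axis=0) - margin * np.array([dx, dy, dz])
    hi = (centres + outer[:, None]).max(axis=0) + margin * np.array([dx, dy, dz])
    centres = centres - lo
    shape_xyz = np.ceil((hi - lo) / np.array([dx, dy, dz])).astype(int) + 1
    if (shape_xyz > spec.max_extent_vox).any():
        raise ValueError(
            f"phantom extent {tuple(shape_xyz)} exceeds max_extent_vox={spec.max_extent_vox}"
        )
    nz, ny, nx = int(shape_xyz[2]), int(shape_xyz[1]), int(shape_xyz[0])

    zz, yy, xx = np.meshgrid(
        np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx, indexing="ij"
    )

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    cavity = np.zeros((nz, ny, nx), dtype=bool)
    shells = []
    for k, (c, r) in enumerate(zip(centres, radii)):
        d2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
        cav = d2 <= r**2
        shells.append(d2 <= (r + spec.wall_um) ** 2)
        labels[cav] = k + 1
        cavity |= cav
    calcite = np.logical_or.reduce(shells) & ~cavity

    septum = np.zeros_like(calcite)
    for k in range(spec.n_chambers - 1):
        septum |= calcite & shells[k] & shells[k + 1]

    # apertures: carve a ball through the centre of each septum; carved
    # voxels join the cavity of the nearer chamber
    if spec.aperture_um > 0:
        for k in range(spec.n_chambers - 1):
            c0, c1 = centres[k], centres[k + 1]
            axis = (c1 - c0) / np.linalg.norm(c1 - c0)
            mid = c0 + axis * (radii[k] + spec.wall_um / 2.0)
            d2 = (xx - mid[0]) ** 2 + (yy - mid[1]) ** 2 + (zz - mid[2]) ** 2
            hole = (d2 <= spec.aperture_um**2) & calcite
            calcite &= ~hole
            septum &= ~hole
            d0 = (xx[hole] - c0[0]) ** 2 + (yy[hole] - c0[1]) ** 2 + (zz[hole] - c0[2]) ** 2
            d1 = (xx[hole] - c1[0]) ** 2 + (yy[hole] - c1[1]) ** 2 + (zz[hole] - c1[2]) ** 2
            labels[hole] = np.where(d0 - radii[k] ** 2 <= d1 - radii[k + 1] ** 2, k + 1, k + 2)
            cavity |= hole

    # septal dissolution: delete a seeded random fraction of septum voxels
    if spec.septum_breach_frac > 0:
        sz, sy, sx = np.nonzero(septum)
        n_del = int(round(spec.septum_breach_frac * sz.size))
        pick = rng.choice(sz.size, size=n_del, replace=False)
        calcite[sz[pick], sy[pick], sx[pick]] = False
        septum[sz[pick], sy[pick], sx[pick]] = False

    # granular infill: seeded random spheres (fine and coarse grains)
    infill = np.zeros_like(cavity)
    if spec.infill_frac > 0:
        target = int(round(spec.infill_frac * cavity.sum()))
        cz, cy, cx = np.nonzero(cavity)
        r_lo, r_hi = spec.infill_grain_radius_vox
        attempts = 0
        while infill.sum() < target and attempts < 50 * spec.n_chambers * 1000:
            attempts += 1
            i = int(rng.integers(cz.size))
            g = int(rng.integers(r_lo, r_hi + 1))
            z0, y0, x0 = int(cz[i]), int(cy[i]), int(cx[i])
            zs = slice(max(z0 - g, 0), min(z0 + g + 1, nz))
            ys = slice(max(y0 - g, 0), min(y0 + g + 1, ny))
            xs = slice(max(x0 - g, 0), min(x0 + g + 1, nx))
            lz, ly, lx = np.ogrid[zs, ys, xs]
            ball = ((lz - z0) * dz) ** 2 + ((ly - y0) * dy) ** 2 + ((lx - x0) * dx) ** 2 <= (
                g * min(dx, dy, dz)
            ) ** 2
            infill[zs, ys, xs] |= ball & cavity[zs, ys, xs]

    bg_i, ca_i, in_i = spec.intensities
    volume = np.full((nz, ny, nx), bg_i, dtype=np.float64)
    volume[calcite] = ca_i
    volume[infill] = in_i
    if spec.noise_sd > 0:
        volume += rng.normal(0.0, spec.noise_sd, size=volume.shape)
    volume = np.clip(np.rint(volume), 0, np.iinfo(np.uint16).max).astype(np.uint16)

    vvol = dx * dy * dz
    chamber_volumes = []
    chamber_centroids = []
    for k in range(spec.n_chambers):
        sel = labels == k + 1
        n = int(sel.sum())
        chamber_volumes.append(n * vvol)
        iz, iy, ix = np.nonzero(sel)
        chamber_centroids.append(
            (float(ix.mean() * dx), float(iy.mean() * dy), float(iz.mean() * dz))
        )

    n_cavity = int((labels > 0).sum())
    n_calcite = int(calcite.sum())
    truth = PhantomTruth(
        chamber_labels=LabelMap(data=labels, spacing=spec.spacing, name="TruthLabels"),
        wall_mask=BinaryMask(data=calcite & ~septum, spacing=spec.spacing, name="TruthWall"),
        septum_mask=BinaryMask(data=septum, spacing=spec.spacing, name="TruthSeptum"),
        infill_mask=BinaryMask(data=infill, spacing=spec.spacing, name="TruthInfill"),
        chamber_volumes_um3=chamber_volumes,
        chamber_centroids_um=chamber_centroids,
        wall_thickness_um=spec.wall_um,
        porosity_pct=100.0 * n_cavity / (n_cavity + n_calcite),
        rng_seed=spec.rng_seed,
    )
    grid = VoxelGrid(data=volume, spacing=spec.spacing, name="Phantom")
    return grid, truth


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    inter = float((a & b).sum())
    total = float(a.sum() + b.sum())
    if total == 0:
        return 1.0
    return 2.0 * inter / total


@dataclass
class RecoveryReport:
    """How faithfully the pipeline recovered a phantom's ground truth."""

    chamber_count_true: int
    chamber_count_est: int
    chamber_count_match: bool
    chamber_volume_rel_err: List[float]
    max_chamber_volume_rel_err: float
    calcite_dice: float
    porosity_true_pct: float
    porosity_est_pct: float
    porosity_err_pp: float
    wall_thickness_true_um: float
    wall_thickness_est_um: float
    wall_thickness_rel_err: float


def recovery_config(spec: PhantomSpec):
    """An analysis configuration matched to a phantom's known contrast.

    Thresholds are the midpoints between the phantom's class intensities
    (the headless analogue of a user reading them off the histogram); the
    smoothing sigma is small for noiseless phantoms, one voxel pitch for
    noisy ones; the wall-split depth is the wall thickness plus one voxel;
    the seed threshold is half the first-chamber radius, which exceeds
    any breach pore by construction.
    """
    from .config import RunConfig

    bg_i, ca_i, in_i = spec.intensities
    min_pitch = min(spec.spacing)
    return RunConfig(
        spacing=spec.spacing,
        infill_enabled=spec.infill_frac > 0,
        infill_lo=(bg_i + in_i) / 2.0 if spec.infill_frac > 0 else None,
        infill_hi=(in_i + ca_i) / 2.0 if spec.infill_frac > 0 else None,
        smooth_sigma_um=min_pitch if spec.noise_sd > 0 else 0.5 * min_pitch,
        skeleton_lo=(bg_i + ca_i) / 2.0,
        skeleton_hi=float(np.iinfo(np.uint16).max),
        fill_close_radius_vox=1 if spec.aperture_um == 0 else 2,
        edt_seal="auto",
        edt_seal_t1_um=max(spec.aperture_um + 2 * min_pitch, 3 * min_pitch),
        edt_seal_t2_um=max(spec.aperture_um + 2 * min_pitch, 3 * min_pitch),
        wall_split_t_um=spec.wall_um + min_pitch,
        chambers_sigma_um=min_pitch,
        chambers_seed_t_um=0.5 * spec.r0_um,
    )


def run_recovery(spec: PhantomSpec, config=None) -> RecoveryReport:
    """Generate a phantom, run the full pipeline on it, score the result."""
    from .pipeline import process

    grid, truth = generate_phantom(spec)
    cfg = config if config is not None else recovery_config(spec)
    products = process(grid, cfg)

    est_records = products.chamber_records
    k_true = truth.chamber_labels.n_labels
    k_est = len(est_records)

    true_vols = sorted(truth.chamber_volumes_um3)
    est_vols = sorted(r.volume_um3 for r in est_records)
    n_pair = min(len(true_vols), len(est_vols))
    rel_err = [
        abs(e - t) / t for e, t in zip(est_vols[:n_pair], true_vols[:n_pair])
    ]

    calcite_dice = dice(products.skeleton.data, truth.calcite_mask)
    porosity_est = products.morphometrics.porosity_pct
    thick_est = products.outer_thickness_summary.mean_um
    return RecoveryReport(
        chamber_count_true=k_true,
        chamber_count_est=k_est,
        chamber_count_match=(k_true == k_est),
        chamber_volume_rel_err=rel_err,
        max_chamber_volume_rel_err=max(rel_err) if rel_err else float("nan"),
        calcite_dice=calcite_dice,
        porosity_true_pct=truth.porosity_pct,
        porosity_est_pct=porosity_est,
        porosity_err_pp=abs(porosity_est - truth.porosity_pct),
        wall_thickness_true_um=truth.wall_thickness_um,
        wall_thickness_est_um=thick_est,
        wall_thickness_rel_err=abs(thick_est - spec.wall_um) / spec.wall_um,
    )
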