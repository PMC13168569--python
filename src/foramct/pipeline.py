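"""The end-to-end segmentation and morphometrics pipeline.

``process`` runs the whole stage sequence in memory on a calibrated grid:
optional infill removal, Gaussian smoothing, band threshold, keep-largest
cleanup, morphological close-fill with an automatic distance-based
sealing fallback, surface area, septa/outer-wall split with thickness
analysis, chamber-space extraction, seeding, connected components,
marker-based watershed and per-chamber statistics.  ``run_single`` wraps
it with file I/O, writing the standard image set, the result CSVs and the
processing log; ``run_batch`` maps ``run_single`` over a directory.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import chambers as ch
from . import fill as fl
from . import metrics as mt
from . import preprocess as pp
from . import wall as wl
from .config import ConfigError, RunConfig
from .grids import BinaryMask, DistanceGrid, LabelMap, VoxelGrid
from .io import (
    ProcessingRecord,
    append_log,
    make_output_dirs,
    read_stack,
    sample_name,
    write_stack,
)


@dataclass
class PipelineProducts:
    """Every image, table and log record produced by one in-memory run."""

    raw: VoxelGrid
    infill_mask: Optional[BinaryMask]
    skeleton: BinaryMask
    filled: BinaryMask
    filled_report: fl.FilledReport
    inner_chambers: BinaryMask
    inner_test: BinaryMask
    outer_test: BinaryMask
    inner_thickness_map: DistanceGrid
    inner_thickness_summary: wl.ThicknessSummary
    outer_thickness_map: DistanceGrid
    outer_thickness_summary: wl.ThicknessSummary
    edge_mask: BinaryMask
    seed_mask: BinaryMask
    seed_distance: DistanceGrid
    labeled_seeds: LabelMap
    watershed_labels: LabelMap
    chamber_records: List[ch.ChamberRecord]
    ordered_chambers: List[ch.OrderedChamber]
    structure_volumes: Dict[str, Tuple[int, float]]
    morphometrics: mt.MorphometricsRecord
    records: List[ProcessingRecord]


def _empty_thickness(mask: BinaryMask) -> Tuple[DistanceGrid, wl.ThicknessSummary]:
    grid = DistanceGrid(
        data=np.zeros(mask.data.shape), spacing=mask.spacing,
        domain="foreground", name=f"{mask.name}ThicknessMap",
    )
    return grid, wl.ThicknessSummary(mean_um=0.0, sd_um=0.0, max_um=0.0, n_voxels=0)


def process(grid: VoxelGrid, cfg: RunConfig) -> PipelineProducts:
    """Run the full stage sequence in memory and return every product."""
    records: List[ProcessingRecord] = []
    t_start = time.perf_counter()

    def rec(step: str, params: dict, t0: float) -> None:
        records.append(
            ProcessingRecord(
                step_name=step, parameters=params,
                elapsed_s=time.perf_counter() - t0,
            )
        )

    # --- optional infill removal -------------------------------------
    raw = VoxelGrid(data=grid.data, spacing=cfg.spacing, name="Raw")
    infill_mask = None
    if cfg.infill_enabled:
        t0 = time.perf_counter()
        rng = pp.ThresholdRange(float(cfg.infill_lo), float(cfg.infill_hi))
        infill_mask = pp.make_infill_mask(raw, rng)
        raw = pp.remove_infill(raw, infill_mask)
        rec("InfillThreshold", {"min": rng.lo, "max": rng.hi}, t0)

    # --- smoothing + calcite threshold -------------------------------
    t0 = time.perf_counter()
    smoothed = pp.gaussian_smooth_3d(raw, cfg.smooth_sigma_um)
    rec("GaussianSmooth", {"sigma_um": cfg.smooth_sigma_um}, t0)

    t0 = time.perf_counter()
    lo = cfg.skeleton_lo
    if lo == "auto":
        lo = float(threshold_otsu(smoothed.data))
    hi = cfg.skeleton_hi
    if hi is None or hi == "auto":
        hi = float(smoothed.data.max())
    skeleton = pp.threshold_range(
        smoothed, pp.ThresholdRange(float(lo), float(hi)), name="SkeletonBinary"
    )
    rec("SkeletonThreshold", {"min": float(lo), "max": float(hi)}, t0)

    t0 = time.perf_counter()
    skeleton = pp.keep_largest_region(skeleton, cfg.connectivity)
    rec("KeepLargestRegion", {"connectivity": cfg.connectivity}, t0)

    # --- fill ----------------------------------------------------------
    t0 = time.perf_counter()
    filled = fl.close_fill(skeleton, cfg.fill_close_radius_vox)
    rec("CloseFill", {"radius_vox": cfg.fill_close_radius_vox}, t0)

    t0 = time.perf_counter()
    report = fl.is_filled(filled, skeleton)
    rec(
        "FilledCheck",
        {
            "is_filled": report.is_filled,
            "unfilled_aperture_count": report.unfilled_aperture_count,
        },
        t0,
    )
    if cfg.edt_seal == "on" or (cfg.edt_seal == "auto" and not report.is_filled):
        t0 = time.perf_counter()
        filled = fl.edt_seal(skeleton, cfg.edt_seal_t1_um, cfg.edt_seal_t2_um)
        rec(
            "EDTSealThreshold",
            {"t1_um": cfg.edt_seal_t1_um, "t2_um": cfg.edt_seal_t2_um},
            t0,
        )

    # --- surface area --------------------------------------------------
    t0 = time.perf_counter()
    area_um2, edge_mask = mt.surface_area(filled)
    rec("SurfaceArea", {"edge_voxels": edge_mask.count}, t0)

    # --- wall split + thickness ---------------------------------------
    t0 = time.perf_counter()
    split_t = cfg.wall_split_t_um
    if split_t == "auto":
        depth = fl.edt(filled, domain="foreground").data
        vals = depth[skeleton.data]
        if np.unique(vals).size < 2:
            split_t = float(np.median(vals))
        else:
            split_t = float(threshold_otsu(vals))
    inner_test, outer_test = wl.split_wall(skeleton, filled, float(split_t))
    rec("WallSplitThreshold", {"t_um": float(split_t)}, t0)

    t0 = time.perf_counter()
    if inner_test.data.any():
        inner_map, inner_sum = wl.local_thickness(inner_test)
    else:  # single-chamber tests have no septa
        inner_map, inner_sum = _empty_thickness(inner_test)
    outer_map, outer_sum = wl.local_thickness(outer_test)
    rec(
        "ThicknessAnalysis",
        {"inner_mean_um": inner_sum.mean_um, "outer_mean_um": outer_sum.mean_um},
        t0,
    )

    # --- chambers ------------------------------------------------------
    t0 = time.perf_counter()
    inner_ch = ch.inner_chambers(filled, skeleton)
    seed_mask, seed_distance, seed_t = ch.make_seeds(
        inner_ch, cfg.chambers_sigma_um, cfg.chambers_seed_t_um
    )
    seed_mask = BinaryMask(
        data=seed_mask.data & inner_ch.data, spacing=seed_mask.spacing, name="SeedImage"
    )
    if not seed_mask.data.any():
        raise ValueError("seed threshold too high: no seed voxels survive")
    rec("SeedThreshold", {"sigma_um": cfg.chambers_sigma_um, "seed_t_um": seed_t}, t0)

    t0 = time.perf_counter()
    labeled_seeds = ch.label_components(seed_mask, connectivity=26)
    rec("ConnectedComponents", {"n_seeds": labeled_seeds.n_labels}, t0)

    t0 = time.perf_counter()
    watershed_labels = ch.watershed_chambers(inner_ch, labeled_seeds, seed_distance)
    rec("Watershed", {"n_chambers": watershed_labels.n_labels}, t0)

    t0 = time.perf_counter()
    chamber_records = ch.chamber_stats(
        watershed_labels, raw, signal=cfg.mean_intensity_signal
    )
    ordered = ch.order_chambers(chamber_records)
    rec("ChamberStats", {"n_chambers": len(chamber_records)}, t0)

    # --- whole-test morphometrics -------------------------------------
    structure_volumes = {
        "SkeletonBinary": mt.mask_volume(skeleton),
        "FilledMask": mt.mask_volume(filled),
        "InnerChambers": mt.mask_volume(inner_ch),
    }
    morpho = mt.MorphometricsRecord(
        calcite_volume_um3=structure_volumes["SkeletonBinary"][1],
        test_volume_um3=structure_volumes["FilledMask"][1],
        chamber_volume_um3=structure_volumes["InnerChambers"][1],
        surface_area_um2=area_um2,
        porosity_pct=mt.porosity(
            structure_volumes["InnerChambers"][1], structure_volumes["FilledMask"][1]
        ),
    )
    records.append(
        ProcessingRecord(
            step_name="TotalProcessingTime",
            parameters={"total_s": round(time.perf_counter() - t_start, 3)},
            elapsed_s=time.perf_counter() - t_start,
        )
    )
    return PipelineProducts(
        raw=raw,
        infill_mask=infill_mask,
        skeleton=skeleton,
        filled=filled,
        filled_report=report,
        inner_chambers=inner_ch,
        inner_test=inner_test,
        outer_test=outer_test,
        inner_thickness_map=inner_map,
        inner_thickness_summary=inner_sum,
        outer_thickness_map=outer_map,
        outer_thickness_summary=outer_sum,
        edge_mask=edge_mask,
        seed_mask=seed_mask,
        seed_distance=seed_distance,
        labeled_seeds=labeled_seeds,
        watershed_labels=watershed_labels,
        chamber_records=chamber_records,
        ordered_chambers=ordered,
        structure_volumes=structure_volumes,
        morphometrics=morpho,
        records=records,
    )


def write_products(
    products: PipelineProducts, sample: str, images_dir: Path, results_dir: Path
) -> List[Path]:
    """Write the standard image set, the eight CSVs and the log."""
    images_dir = Path(images_dir)
    results_dir = Path(results_dir)
    images_dir.mkdir(parents=True, exist_ok=True)
    results_dir.mkdir(parents=True, exist_ok=True)
    stale_log = results_dir / f"{sample}_ProcessingLog.txt"
    if stale_log.exists():
        stale_log.unlink()
    manifest: List[Path] = []
    images = [
        products.raw,
        products.skeleton,
        products.filled,
        products.inner_chambers,
        products.inner_test,
        replace_name(products.inner_thickness_map, "InnerTestThicknessMap"),
        products.outer_test,
        replace_name(products.outer_thickness_map, "OuterTestThicknessMap"),
        products.edge_mask,
        products.watershed_labels,
        products.seed_distance,
        products.seed_mask,
        products.labeled_seeds,
    ]
    if products.infill_mask is not None:
        images.append(products.infill_mask)
    for image in images:
        manifest.append(write_stack(image, images_dir / f"{image.name}.tif"))

    manifest.extend(
        mt.assemble_results(
            sample,
            results_dir,
            structure_volumes=products.structure_volumes,
            surface=(products.edge_mask.count, products.morphometrics.surface_area_um2),
            inner_thickness=products.inner_thickness_summary,
            outer_thickness=products.outer_thickness_summary,
            chamber_records=products.chamber_records,
            ordered_chambers=products.ordered_chambers,
        )
    )
    log_path = None
    for record in products.records:
        log_path = append_log(record, results_dir)
    if log_path is not None:
        manifest.append(log_path)
    return manifest


def replace_name(image, name: str):
    clone = replace(image)
    clone.name = name
    return clone


def run_single(cfg: RunConfig) -> List[Path]:
    """Process one stack on disk; returns the manifest of files written."""
    if cfg.input is None or cfg.out_root is None:
        raise ConfigError("input and out_root are required")
    if cfg.input.suffix.lower() not in (".tif", ".tiff"):
        raise ConfigError(f"input must be a .tif/.tiff file, got {cfg.input.name}")
    grid = read_stack(cfg.input, cfg.spacing)
    sample = sample_name(cfg.input)
    images_dir, results_dir = make_output_dirs(cfg.input, cfg.out_root)
    # a rerun must not append to a stale log
    log = results_dir / f"{sample}_ProcessingLog.txt"
    if log.exists():
        log.unlink()
    products = process(grid, cfg)
    return write_products(products, sample, images_dir, results_dir)


@dataclass
class BatchResult:
    sample: str
    status: str
    elapsed_s: float
    error: str = ""


def run_batch(cfg: RunConfig) -> Tuple[List[BatchResult], Path]:
    """Process every .tif/.tiff in a directory in lexicographic order."""
    if cfg.input is None or not Path(cfg.input).is_dir():
        raise ConfigError("batch mode requires an input directory")
    files = sorted(
        p for p in Path(cfg.input).iterdir()
        if p.suffix.lower() in (".tif", ".tiff") and p.is_file()
    )
    if not files:
        raise ConfigError(f"no .tif/.tiff files in {cfg.input}")
    results: List[BatchResult] = []
    for path in files:
        sub = replace(cfg, input=path, mode="single")
        t0 = time.perf_counter()
        try:
            run_single(sub)
            results.append(
                BatchResult(sample_name(path), "ok", time.perf_counter() - t0)
            )
        except Exception as exc:  # noqa: BLE001 - batch must report any failure
            results.append(
                BatchResult(
                    sample_name(path), "failed", time.perf_counter() - t0, str(exc)
                )
            )
            if cfg.on_error == "halt":
                break
    summary = pd.DataFrame(
        [
            {
                "sample": r.sample,
                "status": r.status,
                "elapsed_s": round(r.elapsed_s, 3),
                "error": r.error,
            }
            for r in results
        ]
    )
    out = Path(cfg.out_root) / "BatchSummary.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out, index=False, lineterminator="\n")
    return results, out

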