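"""Stack I/O, output directory layout and the per-sample processing log.

Every run of the pipeline produces two sibling directories next to the
input stack's chosen output root, ``<Sample>_Images`` and
``<Sample>_Results``, where ``Sample`` is the input filename without its
final extension.  Images are multi-page TIFFs; binary masks are written as
8-bit 0/255, label maps in the smallest unsigned integer type that holds
the maximum label, and float fields (distance/thickness maps) as 32-bit
float.  Voxel calibration is supplied by the user, never read back from
TIFF metadata; the X/Y pixel resolution is nevertheless recorded on write
for downstream viewers.
"""

from __future__ import annotations

import datetime as _dt
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Tuple, Union

import numpy as np
import tifffile

from .grids import BinaryMask, DistanceGrid, LabelMap, Spacing, VoxelGrid

AnyImage = Union[VoxelGrid, BinaryMask, LabelMap, DistanceGrid]

#: characters that are invalid or fragile in file systems; rejected in Sample names
INVALID_NAME_CHARS = set('/\\:*?"<>|')


@dataclass
class ProcessingRecord:
    """One traceability entry: a processing step and the parameters it used."""

    step_name: str
    parameters: Dict[str, object] = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat(timespec="seconds"))
    elapsed_s: float = 0.0

    def __post_init__(self) -> None:
        if self.elapsed_s < 0:
            raise ValueError("elapsed_s must be >= 0")


def read_stack(path: os.PathLike, spacing: Spacing) -> VoxelGrid:
    """Read a greyscale multi-page TIFF into a calibrated (z, y, x) grid.

    Integer dtypes are preserved without rescaling.  RGB / multi-channel
    stacks are rejected: the workflow operates on single-channel µCT data.
    """
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError("voxel spacing must be three positive values (dx, dy, dz) in um")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        if any(ax in series.axes for ax in ("S", "C")):
            raise ValueError(f"{path.name}: not greyscale (channel axis present)")
        data = series.asarray()
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"{path.name}: not greyscale (expected a 3D single-channel stack)")
    return VoxelGrid(data=data, spacing=tuple(spacing), name=sample_name(path))


def write_stack(image: AnyImage, path: os.PathLike) -> Path:
    """Write a grid/mask/label map as a multi-page TIFF.

    Encoding contract: BinaryMask -> uint8 {0, 255}; LabelMap -> smallest
    unsigned dtype holding the max label; DistanceGrid -> float32;
    VoxelGrid -> its own dtype (float64 narrowed to float32).
    """
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(f"{path} is a directory")
    path.parent.mkdir(parents=True, exist_ok=True)

    if isinstance(image, BinaryMask):
        arr = image.data.astype(np.uint8) * 255
    elif isinstance(image, LabelMap):
        mx = int(image.data.max()) if image.data.size else 0
        if mx <= np.iinfo(np.uint8).max:
            dtype = np.uint8
        elif mx <= np.iinfo(np.uint16).max:
            dtype = np.uint16
        else:
            dtype = np.uint32
        arr = image.data.astype(dtype)
    elif isinstance(image, DistanceGrid):
        arr = image.data.astype(np.float32)
    else:
        arr = image.data
        if arr.dtype == np.float64:
            arr = arr.astype(np.float32)

    dx, dy, _dz = image.spacing
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        resolution=(1.0 / dx, 1.0 / dy),
        metadata=None,
        software="foramct",
    )
    return path


def sample_name(input_path: os.PathLike) -> str:
    """Base filename without its final extension (``a.b.c.tiff`` -> ``a.b.c``)."""
    name = Path(input_path).name
    sample = Path(name).stem
    if not sample:
        raise ValueError(f"cannot derive a sample name from {name!r}")
    bad = INVALID_NAME_CHARS.intersection(sample)
    if bad:
        raise ValueError(f"sample name {sample!r} contains invalid characters: {sorted(bad)}")
    return sample


def make_output_dirs(input_path: os.PathLike, out_root: os.PathLike) -> Tuple[Path, Path]:
    """Create (idempotently) ``<Sample>_Images`` and ``<Sample>_Results``."""
    sample = sample_name(input_path)
    out_root = Path(out_root)
    images_dir = out_root / f"{sample}_Images"
    results_dir = out_root / f"{sample}_Results"
    images_dir.mkdir(parents=True, exist_ok=True)
    results_dir.mkdir(parents=True, exist_ok=True)
    return images_dir, results_dir


def _log_path(results_dir: Path) -> Path:
    sample = results_dir.name
    if sample.endswith("_Results"):
        sample = sample[: -len("_Results")]
    return results_dir / f"{sample}_ProcessingLog.txt"


def append_log(record: ProcessingRecord, results_dir: os.PathLike) -> Path:
    """Append one human-readable block to ``<Sample>_ProcessingLog.txt``."""
    results_dir = Path(results_dir)
    if not results_dir.is_dir():
        raise FileNotFoundError(f"results directory {results_dir} does not exist")
    path = _log_path(results_dir)
    lines = [f"[{record.step_name}]"]
    for key, value in record.parameters.items():
        lines.append(f"{key} = {value}")
    lines.append(f"timestamp = {record.timestamp}")
    lines.append(f"elapsed_s = {record.elapsed_s:.3f}")
    lines.append("")
    with open(path, "a", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def parse_log(path: os.PathLike) -> list[ProcessingRecord]:
    """Parse a processing log back into records (used for traceability checks)."""
    text = Path(path).read_text(encoding="utf-8")
    records: list[ProcessingRecord] = []
    current: ProcessingRecord | None = None
    for line in text.splitlines():
        header = re.fullmatch(r"\[(.+)\]", line.strip())
        if header:
            current = ProcessingRecord(step_name=header.group(1), parameters={})
            records.append(current)
            continue
        if current is None or " = " not in line:
            continue
        key, value = line.split(" = ", 1)
        key = key.strip()
        if key == "timestamp":
            current.timestamp = value.strip()
        elif key == "elapsed_s":
            current.elapsed_s = float(value)
        else:
            current.parameters[key] = value.strip()
    return records
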