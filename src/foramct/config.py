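"""Run configuration: the headless replacement for interactive prompts.

Every threshold the original interactive workflow asked the user for is a
config value here; numeric thresholds are taken verbatim, the string
``"auto"`` resolves at run time (Otsu's two-class split for greyscale
thresholds, distribution-based heuristics for the geometric ones) and the
resolved values are logged exactly as user-entered ones would be.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

from .grids import Spacing

Threshold = Union[float, str]  # a number or "auto"


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 1)."""


@dataclass
class RunConfig:
    spacing: Spacing
    input: Optional[Path] = None
    out_root: Optional[Path] = None
    mode: str = "single"            # single | batch
    on_error: str = "halt"          # halt | skip (batch only)
    connectivity: int = 26

    infill_enabled: bool = False
    infill_lo: Optional[float] = None
    infill_hi: Optional[float] = None

    smooth_sigma_um: float = 1.0
    skeleton_lo: Threshold = "auto"
    skeleton_hi: Optional[Threshold] = None  # None -> data maximum

    fill_close_radius_vox: int = 3
    edt_seal: str = "auto"          # auto | on | off
    edt_seal_t1_um: float = 5.0
    edt_seal_t2_um: float = 5.0

    wall_split_t_um: Threshold = "auto"

    chambers_sigma_um: float = 1.0
    chambers_seed_t_um: Threshold = "auto"
    mean_intensity_signal: str = "raw"  # raw | labels

    def __post_init__(self) -> None:
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.input is not None:
            self.input = Path(self.input)
        if self.out_root is not None:
            self.out_root = Path(self.out_root)
        self.validate()

    def validate(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ConfigError("spacing must be three positive values (dx, dy, dz) in um")
        if self.mode not in ("single", "batch"):
            raise ConfigError("mode must be 'single' or 'batch'")
        if self.on_error not in ("halt", "skip"):
            raise ConfigError("on_error must be 'halt' or 'skip'")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.infill_enabled and (self.infill_lo is None or self.infill_hi is None):
            raise ConfigError("infill removal enabled but infill.lo/infill.hi not set")
        if self.smooth_sigma_um < 0 or self.chambers_sigma_um < 0:
            raise ConfigError("gaussian sigmas must be >= 0")
        for name in ("skeleton_lo", "wall_split_t_um", "chambers_seed_t_um"):
            value = getattr(self, name)
            if isinstance(value, str) and value != "auto":
                raise ConfigError(f"{name} must be a number or 'auto'")
        if self.edt_seal not in ("auto", "on", "off"):
            raise ConfigError("fill.edt_seal must be 'auto', 'on' or 'off'")
        if self.edt_seal_t1_um < 0 or self.edt_seal_t2_um < 0:
            raise ConfigError("edt_seal thresholds must be >= 0")
        if self.fill_close_radius_vox < 0:
            raise ConfigError("fill.close_radius_vox must be >= 0")
        if self.mean_intensity_signal not in ("raw", "labels"):
            raise ConfigError("mean_intensity_signal must be 'raw' or 'labels'")


#: dotted config keys -> RunConfig fields
_KEY_MAP = {
    "input": "input",
    "out_root": "out_root",
    "mode": "mode",
    "on_error": "on_error",
    "spacing": "spacing",
    "connectivity": "connectivity",
    "infill.enabled": "infill_enabled",
    "infill.lo": "infill_lo",
    "infill.hi": "infill_hi",
    "smooth.sigma_um": "smooth_sigma_um",
    "skeleton.lo": "skeleton_lo",
    "skeleton.hi": "skeleton_hi",
    "fill.close_radius_vox": "fill_close_radius_vox",
    "fill.edt_seal.enabled": "edt_seal",
    "fill.edt_seal.t1_um": "edt_seal_t1_um",
    "fill.edt_seal.t2_um": "edt_seal_t2_um",
    "wall.split_t_um": "wall_split_t_um",
    "chambers.sigma_um": "chambers_sigma_um",
    "chambers.seed_t_um": "chambers_seed_t_um",
    "chambers.mean_intensity_signal": "mean_intensity_signal",
}


def _flatten(d: dict, prefix: str = "") -> dict:
    out = {}
    for key, value in d.items():
        dotted = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, f"{dotted}."))
        else:
            out[dotted] = value
    return out


def config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a nested or dotted-key mapping."""
    flat = _flatten(raw)
    kwargs = {}
    for dotted, value in flat.items():
        if dotted not in _KEY_MAP:
            raise ConfigError(f"unknown config key: {dotted}")
        kwargs[_KEY_MAP[dotted]] = value
    if "spacing" not in kwargs:
        raise ConfigError("spacing is required")
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:  # wrong value shape for a field
        raise ConfigError(str(exc)) from exc


def config_from_yaml(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw)
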