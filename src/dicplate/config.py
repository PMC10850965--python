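"""Run configuration: YAML loading, validation and round-tripping.

Precedence is flags > config file > defaults; the CLI applies flag
overrides after loading.  Unknown keys are rejected rather than ignored so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .colorimetry import ANALYTICAL_CHANNELS
from .errors import ConfigurationError
from .plate_reader import GridSpec

_VALID_CHANNELS = ANALYTICAL_CHANNELS + ("auto",)

_TOP_KEYS = {"grid", "roi", "mask", "channel", "r2_min", "backcalc_bias_max", "seed"}
_GRID_KEYS = {"rows", "cols", "pitch_px", "first_center_px", "well_radius_px"}
_ROI_KEYS = {"radius_px"}
_MASK_KEYS = {"k_mad", "glare_min", "reject_fraction"}


@dataclass
class RunConfig:
    """All pipeline knobs in one validated object."""

    grid_rows: int = 1
    grid_cols: int = 8
    grid_pitch_px: float = 70.0
    grid_first_center_px: tuple[float, float] = (45.0, 45.0)
    grid_well_radius_px: float = 30.0
    roi_radius_px: float = 25.0
    mask_k_mad: float = 3.5
    mask_glare_min: float = 250.0
    mask_reject_fraction: float = 0.30
    channel: str = "blue"
    r2_min: float = 0.98
    backcalc_bias_max: float = 15.0
    seed: int | None = None

    def __post_init__(self):
        if self.channel not in _VALID_CHANNELS:
            raise ConfigurationError(
                f"channel must be one of {_VALID_CHANNELS}, got {self.channel!r}"
            )
        if not (0.0 < self.r2_min <= 1.0):
            raise ConfigurationError("r2_min must lie in (0, 1]")
        if self.backcalc_bias_max <= 0:
            raise ConfigurationError("backcalc_bias_max must be positive")
        if not (0.0 <= self.mask_reject_fraction <= 1.0):
            raise ConfigurationError("mask.reject_fraction must lie in [0, 1]")
        if self.mask_k_mad <= 0:
            raise ConfigurationError("mask.k_mad must be positive")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ConfigurationError("grid must have at least one row and column")
        if self.roi_radius_px >= self.grid_well_radius_px:
            raise ConfigurationError("roi.radius_px must be smaller than well radius")

    def grid_spec(self) -> GridSpec:
        return GridSpec(
            rows=self.grid_rows,
            cols=self.grid_cols,
            pitch_px=self.grid_pitch_px,
            first_center_px=tuple(self.grid_first_center_px),
            well_radius_px=self.grid_well_radius_px,
            roi_radius_px=self.roi_radius_px,
        )

    def to_dict(self) -> dict:
        return {
            "grid": {
                "rows": self.grid_rows,
                "cols": self.grid_cols,
                "pitch_px": self.grid_pitch_px,
                "first_center_px": list(self.grid_first_center_px),
                "well_radius_px": self.grid_well_radius_px,
            },
            "roi": {"radius_px": self.roi_radius_px},
            "mask": {
                "k_mad": self.mask_k_mad,
                "glare_min": self.mask_glare_min,
                "reject_fraction": self.mask_reject_fraction,
            },
            "channel": self.channel,
            "r2_min": self.r2_min,
            "backcalc_bias_max": self.backcalc_bias_max,
            "seed": self.seed,
        }


def _check_keys(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {context} config keys: {sorted(unknown)}")


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")
    grid = raw.get("grid", {}) or {}
    roi = raw.get("roi", {}) or {}
    mask = raw.get("mask", {}) or {}
    _check_keys(grid, _GRID_KEYS, "grid")
    _check_keys(roi, _ROI_KEYS, "roi")
    _check_keys(mask, _MASK_KEYS, "mask")
    defaults = RunConfig()
    first = grid.get("first_center_px", list(defaults.grid_first_center_px))
    if not (isinstance(first, (list, tuple)) and len(first) == 2):
        raise ConfigurationError("grid.first_center_px must be a [row, col] pair")
    return RunConfig(
        grid_rows=int(grid.get("rows", defaults.grid_rows)),
        grid_cols=int(grid.get("cols", defaults.grid_cols)),
        grid_pitch_px=float(grid.get("pitch_px", defaults.grid_pitch_px)),
        grid_first_center_px=(float(first[0]), float(first[1])),
        grid_well_radius_px=float(grid.get("well_radius_px", defaults.grid_well_radius_px)),
        roi_radius_px=float(roi.get("radius_px", defaults.roi_radius_px)),
        mask_k_mad=float(mask.get("k_mad", defaults.mask_k_mad)),
        mask_glare_min=float(mask.get("glare_min", defaults.mask_glare_min)),
        mask_reject_fraction=float(mask.get("reject_fraction", defaults.mask_reject_fraction)),
        channel=str(raw.get("channel", defaults.channel)),
        r2_min=float(raw.get("r2_min", defaults.r2_min)),
        backcalc_bias_max=float(raw.get("backcalc_bias_max", defaults.backcalc_bias_max)),
        seed=None if raw.get("seed") is None else int(raw["seed"]),
    )


def load_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def dump_config(config: RunConfig, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
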