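"""Synthetic plate-image simulator with ground-truth manifests.

Renders microstrip photos from a configurable concentration -> color
response model so that every pipeline stage (well localization, masking,
ROI statistics, calibration, quantification, validation) can be exercised
against known truth without real photographs.

The response model is phenomenological: each RGB channel responds linearly
to analyte concentration between a low and a high clipping bound.  The low
bound mimics the loss of proportionality when the analyte no longer limits
the oxidant (residual dye color stops changing); defaults reproduce the
blue-channel line -3.009x + 128.19 with clipping below 2.52 % w/w in an
o/w cream matrix, and the weaker red/green responses.  HSB responses are
emergent from the rendered RGB, not separately parameterized.

Noise enters at three levels, mirroring how a lightbox photograph varies:
per-pixel Gaussian sensor/texture noise, a per-well multiplicative
illumination gain, and a per-photo (run) multiplicative gain shared by all
wells.  The run gain is why standards and unknowns must share a photo —
in-photo calibration cancels it.  Gain draws are clamped to [0.6, 1.3]:
a smartphone camera's automatic brightness adjustment keeps exposure in
range, so a photo is never grossly over- or under-exposed however much the
ambient illumination varies.  Glare discs and bubble rings can be injected
to exercise artifact masking; they are off by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, LayoutError
from .plate_reader import (
    PLATE_MAP_COLUMNS,
    GridSpec,
    PlateImage,
    disc_indices,
    save_image,
)

#: Default calibration-standard levels for simulated studies, % w/w.
DEFAULT_STANDARD_LEVELS = (2.52, 6.03, 10.07, 18.13, 23.32, 27.21, 30.03)

#: Default QC levels for a simulated validation study, % w/w.
DEFAULT_QC_LEVELS = (6.03, 10.07, 18.13, 23.32, 27.21, 30.03)

#: Gain clamp emulating the camera's automatic exposure adjustment.
GAIN_BOUNDS = (0.6, 1.3)


def _draw_gain(rng: np.random.Generator, sd: float) -> float:
    # always consume one draw so the random stream (and hence every other
    # noise realization) is identical across gain settings
    z = rng.normal(0.0, 1.0)
    if sd <= 0:
        return 1.0
    return float(np.clip(1.0 + sd * z, *GAIN_BOUNDS))


@dataclass(frozen=True)
class ChannelResponse:
    """Linear response of one RGB channel with low/high concentration clipping."""

    intercept: float  # intensity at zero (clipped) analyte
    slope: float  # intensity per % w/w
    clip_lo: float  # % w/w below which the response is flat
    clip_hi: float  # % w/w above which the response is flat

    def __post_init__(self):
        if not (0.0 <= self.intercept <= 255.0):
            raise DomainError(f"intercept {self.intercept} outside [0, 255]")
        if not self.clip_lo < self.clip_hi:
            raise DomainError("clip_lo must be < clip_hi")


@dataclass(frozen=True)
class ResponseModel:
    """Simulator ground truth: per-channel responses, noise and artifacts.

    Default per-channel lines and clipping bounds follow the cream-matrix
    urea/methyl-red/hypochlorite chemistry; noise magnitudes are simulator
    choices representative of a lightbox smartphone photo.
    """

    red: ChannelResponse = ChannelResponse(187.04, -0.255, 8.1, 30.03)
    green: ChannelResponse = ChannelResponse(171.90, -0.452, 8.1, 30.03)
    blue: ChannelResponse = ChannelResponse(128.19, -3.009, 2.52, 30.03)
    pixel_noise_sd: float = 6.0
    well_gain_sd: float = 0.01
    run_gain_sd: float = 0.05
    glare_prob: float = 0.0
    bubble_prob: float = 0.0
    background_rgb: tuple[float, float, float] = (250.0, 247.0, 242.0)
    reaction_meta: dict = field(
        default_factory=lambda: {"methyl_red_ug_per_g": 22.8, "naocl_mg_per_g": 1.51}
    )

    def __post_init__(self):
        for sd in (self.pixel_noise_sd, self.well_gain_sd, self.run_gain_sd):
            if sd < 0:
                raise DomainError("noise standard deviations must be >= 0")

    def channel(self, name: str) -> ChannelResponse:
        if name not in ("red", "green", "blue"):
            raise DomainError(f"no rendered response for channel {name!r}")
        return getattr(self, name)

    def noiseless(self) -> "ResponseModel":
        """Copy with all noise and artifact sources switched off."""
        return replace(
            self,
            pixel_noise_sd=0.0,
            well_gain_sd=0.0,
            run_gain_sd=0.0,
            glare_prob=0.0,
            bubble_prob=0.0,
        )


#: Qualitative matrix presets: same chemistry, matrix-dependent linear range
#: and background tint (an opaque color-free cream vs a light-brown shampoo).
MATRIX_PRESETS: dict[str, ResponseModel] = {
    "cream_b": ResponseModel(),
    "cream_c": replace(
        ResponseModel(),
        red=ChannelResponse(187.04, -0.255, 8.1, 21.1),
        green=ChannelResponse(171.90, -0.452, 8.1, 21.1),
        blue=ChannelResponse(128.19, -3.009, 2.5, 21.1),
    ),
    "shampoo_a": replace(
        ResponseModel(),
        red=ChannelResponse(187.04, -0.255, 8.1, 27.2),
        green=ChannelResponse(171.90, -0.452, 8.1, 27.2),
        blue=ChannelResponse(128.19, -3.009, 2.5, 27.2),
        background_rgb=(235.0, 220.0, 195.0),
    ),
}


def expected_signal(model: ResponseModel, channel: str, conc: float) -> float:
    """Pre-noise channel intensity at a concentration (% w/w).

    The concentration is clamped to [clip_lo, clip_hi] before the line is
    evaluated; the result is clamped to [0, 255].
    """
    if conc < 0:
        raise DomainError(f"concentration must be >= 0, got {conc}")
    ch = model.channel(channel)
    c = min(max(conc, ch.clip_lo), ch.clip_hi)
    return float(np.clip(ch.intercept + ch.slope * c, 0.0, 255.0))


def expected_rgb(model: ResponseModel, conc: float) -> tuple[float, float, float]:
    return tuple(expected_signal(model, ch, conc) for ch in ("red", "green", "blue"))


def strip_grid(n_wells: int, rows: int = 1, pitch_px: float = 70.0,
               margin_px: float = 45.0, well_radius_px: float = 30.0,
               roi_radius_px: float = 25.0) -> GridSpec:
    """A simple row-major strip layout sized to hold ``n_wells``."""
    if n_wells <= 0 or n_wells % rows:
        raise LayoutError(f"cannot arrange {n_wells} wells in {rows} row(s)")
    return GridSpec(
        rows=rows,
        cols=n_wells // rows,
        pitch_px=pitch_px,
        first_center_px=(margin_px, margin_px),
        well_radius_px=well_radius_px,
        roi_radius_px=roi_radius_px,
    )


def grid_image_shape(grid: GridSpec) -> tuple[int, int]:
    r0, c0 = grid.first_center_px
    h = int(np.ceil(2 * r0 + (grid.rows - 1) * grid.pitch_px))
    w = int(np.ceil(2 * c0 + (grid.cols - 1) * grid.pitch_px))
    return max(h, 64), max(w, 64)


@dataclass
class PlateManifest:
    """Ground truth for one rendered plate: the oracle for pipeline tests."""

    seed: int | None
    run_gain: float
    wells: list  # of per-well truth dicts

    def to_dict(self) -> dict:
        return {"seed": self.seed, "run_gain": self.run_gain, "wells": self.wells}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PlateManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(seed=d["seed"], run_gain=d["run_gain"], wells=d["wells"])


def _true_conc(row) -> float:
    nominal = row.get("nominal_conc")
    added = row.get("added_conc")
    nominal = 0.0 if nominal is None or pd.isna(nominal) else float(nominal)
    added = 0.0 if added is None or pd.isna(added) else float(added)
    if row["role"] == "blank":
        return 0.0
    return nominal + added


def render_plate(
    model: ResponseModel,
    plate_map: pd.DataFrame,
    grid: GridSpec,
    seed: int | np.random.Generator | None = 0,
) -> tuple[PlateImage, PlateManifest]:
    """Render one plate photo plus its manifest.

    Wells are filled in plate-map order (row-major grid positions) with
    their expected RGB times the run gain times a per-well gain; glare
    discs / bubble rings are injected per probability; per-pixel Gaussian
    noise is added over the whole frame and the result quantized to 8 bits.
    Identical (model, plate_map, grid, seed) inputs give byte-identical
    images.
    """
    n_wells = grid.rows * grid.cols
    if len(plate_map) != n_wells:
        raise LayoutError(f"plate map has {len(plate_map)} rows for {n_wells} grid wells")
    if grid.pitch_px < 2 * grid.well_radius_px:
        raise LayoutError("wells overlap: pitch smaller than well diameter")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    h, w = grid_image_shape(grid)
    frame = np.empty((h, w, 3), dtype=float)
    frame[:, :] = np.asarray(model.background_rgb, dtype=float)

    run_gain = _draw_gain(rng, model.run_gain_sd)
    frame *= run_gain

    centers = [
        (grid.first_center_px[0] + i * grid.pitch_px,
         grid.first_center_px[1] + j * grid.pitch_px)
        for i in range(grid.rows)
        for j in range(grid.cols)
    ]
    wells = []
    for (_, row), center in zip(plate_map.iterrows(), centers):
        conc = _true_conc(row)
        base_rgb = expected_rgb(model, conc)
        well_gain = _draw_gain(rng, model.well_gain_sd)
        rendered = tuple(v * run_gain * well_gain for v in base_rgb)
        rr, cc = disc_indices(center, grid.well_radius_px, (h, w))
        frame[rr, cc, :] = np.asarray(rendered, dtype=float)

        # artifact draws happen unconditionally so the stream is stable
        glare_u, bubble_u = rng.random(2)
        art_angle, art_dist = rng.random(2)
        glare = glare_u < model.glare_prob
        bubble = bubble_u < model.bubble_prob
        angle = 2 * np.pi * art_angle
        dist = art_dist * grid.roi_radius_px * 0.5
        art_center = (center[0] + dist * np.sin(angle), center[1] + dist * np.cos(angle))
        if glare:
            gr, gc = disc_indices(art_center, grid.roi_radius_px * 0.35, (h, w))
            frame[gr, gc, :] = 255.0
        if bubble:
            br_, bc_ = disc_indices(art_center, grid.roi_radius_px * 0.35, (h, w))
            ir, ic = disc_indices(art_center, grid.roi_radius_px * 0.20, (h, w))
            ring = np.ones((h, w), dtype=bool) & False
            ring[br_, bc_] = True
            ring[ir, ic] = False
            frame[ring] *= 0.45

        wells.append(
            {
                "well_id": str(row["well_id"]),
                "role": str(row["role"]),
                "matrix": str(row["matrix"]),
                "true_conc": conc,
                "center": [float(center[0]), float(center[1])],
                "response_rgb": [float(v) for v in base_rgb],
                "rendered_rgb": [float(v) for v in rendered],
                "well_gain": well_gain,
                "glare": bool(glare),
                "bubble": bool(bubble),
            }
        )

    # drawn unconditionally (then scaled) so the stream matches across settings
    noise = rng.normal(0.0, 1.0, size=frame.shape) * model.pixel_noise_sd
    # dithered (stochastic) 8-bit quantization: floor(v + U[0,1)) has mean v,
    # like a real sensor whose read noise spans at least one LSB
    dither = rng.random(size=frame.shape)
    quantized = np.clip(np.floor(frame + noise + dither), 0, 255).astype(np.uint8)
    image = PlateImage(
        pixels=quantized,
        capture_meta={"simulated": True, "run_gain": run_gain, "seed": seed_val},
    )
    return image, PlateManifest(seed=seed_val, run_gain=run_gain, wells=wells)


def make_plate_map(entries) -> pd.DataFrame:
    """Build a plate-map frame from (well_id, role, matrix, nominal, added) tuples."""
    return pd.DataFrame(entries, columns=list(PLATE_MAP_COLUMNS))


def standards_plate_map(
    levels=DEFAULT_STANDARD_LEVELS, matrix: str = "cream_b", qc_levels=(), prefix: str = "W"
) -> pd.DataFrame:
    """Plate map with one standard well per level plus optional QC wells."""
    entries = [
        (f"{prefix}{i + 1:02d}", "standard", matrix, float(c), None)
        for i, c in enumerate(levels)
    ]
    for j, c in enumerate(qc_levels):
        entries.append((f"{prefix}Q{j + 1:02d}", "qc", matrix, float(c), None))
    return make_plate_map(entries)


@dataclass
class SimulatedRun:
    """One simulated photo with everything the pipeline needs, in memory."""

    run_id: str
    image: PlateImage
    plate_map: pd.DataFrame
    grid: GridSpec
    manifest: PlateManifest


def simulate_validation_study(
    model: ResponseModel,
    levels=DEFAULT_QC_LEVELS,
    n_runs: int = 8,
    seed: int = 0,
    standard_levels=DEFAULT_STANDARD_LEVELS,
    matrix: str = "cream_b",
) -> list[SimulatedRun]:
    """Simulate an intermediate-precision study: ``n_runs`` independent photos.

    Each run is a separate photo holding its own calibration standards (at
    ``standard_levels``) plus one QC well per requested level, with a fresh
    run-level gain — the simulator's model of "different analysis
    conditions".  Run seeds are spawned from ``seed`` so the whole study is
    reproducible.
    """
    levels = tuple(float(c) for c in levels)
    for c in levels:
        if not 0 < c <= max(s for s in standard_levels):
            raise DomainError(f"QC level {c} outside the simulated standard span")
    children = np.random.SeedSequence(seed).spawn(n_runs)
    grid = strip_grid(len(standard_levels) + len(levels))
    runs = []
    for i, child in enumerate(children):
        plate_map = standards_plate_map(standard_levels, matrix=matrix, qc_levels=levels)
        rng = np.random.default_rng(child)
        image, manifest = render_plate(model, plate_map, grid, seed=rng)
        manifest.seed = int(seed)
        runs.append(
            SimulatedRun(
                run_id=f"run_{i:02d}",
                image=image,
                plate_map=plate_map,
                grid=grid,
                manifest=manifest,
            )
        )
    return runs


def _grid_to_yaml_dict(grid: GridSpec) -> dict:
    return {
        "grid": {
            "rows": grid.rows,
            "cols": grid.cols,
            "pitch_px": grid.pitch_px,
            "first_center_px": list(grid.first_center_px),
            "well_radius_px": grid.well_radius_px,
        },
        "roi": {"radius_px": grid.roi_radius_px},
    }


def write_run(run: SimulatedRun, run_dir) -> Path:
    """Write one simulated run (image, plate map, layout, manifest) to disk."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    save_image(run.image, run_dir / "plate.png")
    run.plate_map.to_csv(run_dir / "plate_map.csv", index=False)
    with open(run_dir / "layout.yaml", "w") as fh:
        yaml.safe_dump(_grid_to_yaml_dict(run.grid), fh, sort_keys=False)
    run.manifest.to_json(run_dir / "manifest.json")
    return run_dir


def write_study(runs: list[SimulatedRun], study_dir, levels=None, seed: int | None = None) -> Path:
    """Write a whole study directory with a study.json index."""
    study_dir = Path(study_dir)
    study_dir.mkdir(parents=True, exist_ok=True)
    for run in runs:
        write_run(run, study_dir / run.run_id)
    index = {
        "runs": [run.run_id for run in runs],
        "seed": seed,
        "levels": list(levels) if levels is not None else None,
    }
    with open(study_dir / "study.json", "w") as fh:
        json.dump(index, fh, indent=2)
    return study_dir
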