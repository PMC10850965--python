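"""Plate photo -> per-well observations.

A plate photo shows a microstrip of wells filled with dye-treated
formulation.  The reader places a configured grid of well centers on the
image, refines each center toward the local color mass, carves a circular
ROI well inside the well (avoiding reflective well edges), masks glare and
bubble pixels, and reduces each ROI to ChannelStats.

ROI discs default to radius 25 px (area ~1963 px^2), within the 1500-2200
px^2 band appropriate for a well photographed at ~1x from ~23 cm.
Coordinates are 0-based (row, col) with origin at the top-left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorimetry import ChannelStats, roi_channel_stats
from .errors import ConfigurationError, DegenerateROIError, DomainError, LayoutError

logger = logging.getLogger(__name__)

#: Recognized well roles on a plate map.
ROLES = ("standard", "qc", "sample", "spiked_sample", "reference_standard", "blank")

#: Acceptable ROI disc area band in px^2 (default radius 25 -> ~1963 px^2).
ROI_AREA_BAND = (1500.0, 2200.0)

#: Plate-map CSV column order.
PLATE_MAP_COLUMNS = ("well_id", "role", "matrix", "nominal_conc", "added_conc")

#: Default limit on the masked fraction before a well is rejected outright.
DEFAULT_REJECT_FRACTION = 0.30


@dataclass
class PlateImage:
    """8-bit RGB raster plus free-form capture metadata."""

    pixels: np.ndarray
    capture_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DomainError(f"expected (H, W, 3) image, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise DomainError("image must be at least 64x64 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise DomainError("image intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def load_image(path, capture_meta: dict | None = None) -> PlateImage:
    """Load a PNG/TIFF photo as an 8-bit RGB PlateImage.

    16-bit input is linearly rescaled to 0-255 (logged); an alpha channel,
    if present, is dropped.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        logger.info("16-bit image %s rescaled to 8-bit", path)
        arr = (arr.astype(float) / 257.0).round().astype(np.uint8)
    return PlateImage(pixels=arr, capture_meta=dict(capture_meta or {}))


def save_image(image: PlateImage, path) -> None:
    iio.imwrite(Path(path), image.pixels)


@dataclass(frozen=True)
class GridSpec:
    """Approximate well-grid geometry supplied by the user/config."""

    rows: int
    cols: int
    pitch_px: float
    first_center_px: tuple[float, float]  # (row, col) of the top-left well
    well_radius_px: float = 30.0
    roi_radius_px: float = 25.0


@dataclass(frozen=True)
class WellLayout:
    """Refined well centers plus ROI geometry, all in pixel units."""

    n_wells: int
    centers: tuple  # of (row, col) float pairs, row-major well order
    well_radius_px: float
    roi_radius_px: float


def _grid_centers(grid: GridSpec):
    r0, c0 = grid.first_center_px
    return [
        (r0 + i * grid.pitch_px, c0 + j * grid.pitch_px)
        for i in range(grid.rows)
        for j in range(grid.cols)
    ]


def _check_disc_inside(center, radius, shape, what: str) -> None:
    r, c = center
    h, w = shape
    if r - radius < -0.5 or c - radius < -0.5 or r + radius > h - 0.5 or c + radius > w - 0.5:
        raise LayoutError(f"{what} at ({r:.1f}, {c:.1f}) r={radius:.1f} leaves the {h}x{w} image")


def locate_wells(image: PlateImage, grid: GridSpec, roi_area_band=ROI_AREA_BAND) -> WellLayout:
    """Refine grid-specified well centers against the image.

    Each approximate center moves to the intensity-weighted centroid of
    (255 - brightness) within a window of half-width pitch/2, where
    brightness is max(R, G, B): the colored well is darker than the white
    strip background, so the centroid tracks the well.  The refinement
    shift is bounded to +/- 0.25 * pitch per axis.

    Raises
    ------
    LayoutError
        If the grid or any refined ROI leaves the image, or the ROI disc
        area falls outside ``roi_area_band``.
    """
    if grid.roi_radius_px >= grid.well_radius_px:
        raise LayoutError("roi_radius_px must be smaller than well_radius_px")
    roi_area = np.pi * grid.roi_radius_px**2
    lo, hi = roi_area_band
    if not (lo <= roi_area <= hi):
        raise LayoutError(
            f"ROI disc area {roi_area:.0f} px^2 outside the configured band [{lo:.0f}, {hi:.0f}]"
        )
    h, w = image.shape
    brightness = image.pixels.max(axis=2).astype(float)
    weight_src = 255.0 - brightness
    half = grid.pitch_px / 2.0
    bound = 0.25 * grid.pitch_px

    refined = []
    for (r, c) in _grid_centers(grid):
        _check_disc_inside((r, c), grid.well_radius_px, (h, w), "well disc (grid guess)")
        r_lo = max(int(np.floor(r - half)), 0)
        r_hi = min(int(np.ceil(r + half)) + 1, h)
        c_lo = max(int(np.floor(c - half)), 0)
        c_hi = min(int(np.ceil(c + half)) + 1, w)
        win = weight_src[r_lo:r_hi, c_lo:c_hi]
        total = win.sum()
        if total > 0:
            rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
            cr = float((win * rr).sum() / total)
            cc_ = float((win * cc).sum() / total)
        else:
            cr, cc_ = r, c
        cr = float(np.clip(cr, r - bound, r + bound))
        cc_ = float(np.clip(cc_, c - bound, c + bound))
        _check_disc_inside((cr, cc_), grid.roi_radius_px, (h, w), "refined ROI disc")
        refined.append((cr, cc_))
    return WellLayout(
        n_wells=len(refined),
        centers=tuple(refined),
        well_radius_px=grid.well_radius_px,
        roi_radius_px=grid.roi_radius_px,
    )


def disc_indices(center, radius, shape):
    """Row/col index arrays of the pixels whose centers fall in the disc."""
    r, c = center
    h, w = shape
    r_lo = max(int(np.floor(r - radius)), 0)
    r_hi = min(int(np.ceil(r + radius)) + 1, h)
    c_lo = max(int(np.floor(c - radius)), 0)
    c_hi = min(int(np.ceil(c + radius)) + 1, w)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    inside = (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
    return rr[inside], cc[inside]


def extract_roi(image: PlateImage, center, radius) -> np.ndarray:
    """Return the (N, 3) pixel array of a circular ROI."""
    rr, cc = disc_indices(center, radius, image.shape)
    return image.pixels[rr, cc, :]


def mask_artifacts(roi_pixels, k_mad: float = 3.5, glare_brightness_min: float = 250.0):
    """Flag glare/bubble pixels within one ROI.

    A pixel is masked iff its brightness (max of RGB) reaches
    ``glare_brightness_min`` or any channel deviates from the ROI channel
    median by more than ``k_mad * 1.4826 * MAD``.  A channel with zero MAD
    (perfectly uniform) contributes no outlier criterion.

    Returns a boolean vector, True = masked.
    """
    px = np.asarray(roi_pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3:
        raise DomainError(f"expected (N, 3) ROI pixels, got shape {px.shape}")
    if px.shape[0] < 100:
        raise DegenerateROIError(f"ROI has only {px.shape[0]} pixels (< 100)")
    mask = px.max(axis=1) >= glare_brightness_min
    med = np.median(px, axis=0)
    mad = np.median(np.abs(px - med), axis=0)
    for ch in range(3):
        if mad[ch] > 0:
            cutoff = k_mad * 1.4826 * mad[ch]
            mask |= np.abs(px[:, ch] - med[ch]) > cutoff
    return mask


@dataclass
class WellObservation:
    """One well's identity, role, concentrations and extracted statistics."""

    well_id: str
    role: str
    matrix: str
    nominal_conc: float | None
    added_conc: float | None
    stats: ChannelStats | None
    masked_fraction: float
    valid: bool

    def signal(self, channel: str) -> float:
        if self.stats is None:
            raise DegenerateROIError(f"well {self.well_id} has no usable statistics")
        return self.stats.signal(channel)


def _parse_conc(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def load_plate_map(path) -> pd.DataFrame:
    """Read a plate-map CSV (well_id, role, matrix, nominal_conc, added_conc)."""
    df = pd.read_csv(path, dtype={"well_id": str, "role": str, "matrix": str})
    missing = set(PLATE_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"plate map {path} missing columns {sorted(missing)}")
    return df


def read_plate(
    image: PlateImage,
    layout: WellLayout,
    plate_map: pd.DataFrame,
    *,
    k_mad: float = 3.5,
    glare_min: float = 250.0,
    reject_fraction: float = DEFAULT_REJECT_FRACTION,
) -> list[WellObservation]:
    """Extract one WellObservation per well.

    The plate map rows are assigned to wells in row-major layout order and
    must match the layout 1:1.  Wells whose masked fraction exceeds
    ``reject_fraction`` (or that end with fewer than 100 usable pixels) are
    flagged invalid with a logged warning; they must not be used downstream.

    Raises
    ------
    ConfigurationError
        If the plate map does not cover the layout exactly or uses an
        unknown role.
    """
    if len(plate_map) != layout.n_wells:
        raise ConfigurationError(
            f"plate map lists {len(plate_map)} wells but the layout has {layout.n_wells}"
        )
    bad_roles = set(plate_map["role"]) - set(ROLES)
    if bad_roles:
        raise ConfigurationError(f"unknown roles in plate map: {sorted(bad_roles)}")

    observations = []
    for (_, row), center in zip(plate_map.iterrows(), layout.centers):
        roi = extract_roi(image, center, layout.roi_radius_px)
        mask = mask_artifacts(roi, k_mad=k_mad, glare_brightness_min=glare_min)
        masked_fraction = float(mask.mean())
        stats = None
        valid = masked_fraction <= reject_fraction
        try:
            stats = roi_channel_stats(roi, mask)
        except DegenerateROIError:
            valid = False
        if not valid:
            logger.warning(
                "well %s rejected: masked_fraction=%.2f (limit %.2f)",
                row["well_id"], masked_fraction, reject_fraction,
            )
        observations.append(
            WellObservation(
                well_id=str(row["well_id"]),
                role=str(row["role"]),
                matrix=str(row["matrix"]),
                nominal_conc=_parse_conc(row["nominal_conc"]),
                added_conc=_parse_conc(row["added_conc"]),
                stats=stats,
                masked_fraction=masked_fraction,
                valid=valid,
            )
        )
    return observations


def observations_to_frame(observations: list[WellObservation]) -> pd.DataFrame:
    """Tabulate observations in the documented CSV column order."""
    rows = []
    for obs in observations:
        s = obs.stats
        rows.append(
            {
                "well_id": obs.well_id,
                "role": obs.role,
                "matrix": obs.matrix,
                "nominal_conc": obs.nominal_conc,
                "added_conc": obs.added_conc,
                "red_mean": s.red_mean if s else np.nan,
                "green_mean": s.green_mean if s else np.nan,
                "blue_mean": s.blue_mean if s else np.nan,
                "rgb_mean": s.rgb_mean if s else np.nan,
                "hue_mean": s.hue_mean if s else np.nan,
                "saturation_mean": s.saturation_mean if s else np.nan,
                "brightness_mean": s.brightness_mean if s else np.nan,
                "masked_fraction": obs.masked_fraction,
                "valid": obs.valid,
            }
        )
    return pd.DataFrame(rows)
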