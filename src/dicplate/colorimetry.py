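"""Pure color math for well colorimetry.

The analytical signal of a colorimetric well is a per-channel mean intensity
over a region of interest (ROI).  Channels are the three RGB planes, their
arithmetic mean, and the HSB (hue/saturation/brightness) planes.  Following
the ImageJ convention, all HSB channels are expressed on the same 0-255
scale as the 8-bit RGB data: hue is degrees rescaled by 255/360, saturation
is 255*(1 - min/max) and brightness is max(R, G, B).

HSB well statistics are means of *per-pixel* HSB values, not the HSB of the
mean RGB color.  The distinction matters: a half-red/half-blue ROI averages
to a gray RGB color (zero saturation) while every individual pixel is fully
saturated.  Per-pixel averaging is what makes saturation a usable analytical
channel for strongly colored wells.

Hue is averaged arithmetically, not circularly.  Hue is never used as the
analytical channel (it shows no linear concentration dependence for this
chemistry), so wrap-around near 0/255 is a documented limitation rather
than a practical one.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .errors import DegenerateROIError, DomainError

#: All channels a ChannelStats carries, in canonical order.
CHANNELS = ("red", "green", "blue", "rgb_mean", "hue", "saturation", "brightness")

#: Channels eligible as an analytical signal (hue excluded a priori).
ANALYTICAL_CHANNELS = ("red", "green", "blue", "rgb_mean", "saturation", "brightness")

#: Minimum number of unmasked pixels for a trustworthy ROI statistic.
MIN_ROI_PIXELS = 100


def _hsb_pixels(pixels: np.ndarray) -> np.ndarray:
    """Vectorized RGB -> HSB on an (N, 3) float array, all planes 0-255.

    Ties between channels are broken in R, G, B priority order, matching
    colorsys/matplotlib.
    """
    px = np.asarray(pixels, dtype=float)
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    mx = px.max(axis=1)
    mn = px.min(axis=1)
    delta = mx - mn

    h = np.zeros_like(mx)
    nz = delta > 0
    safe = np.where(nz, delta, 1.0)
    is_r = nz & (r == mx)
    is_g = nz & ~is_r & (g == mx)
    is_b = nz & ~is_r & ~is_g
    # hue in "sextant" units (0-6), then scaled to 0-255
    h = np.where(is_r, ((g - b) / safe) % 6.0, h)
    h = np.where(is_g, (b - r) / safe + 2.0, h)
    h = np.where(is_b, (r - g) / safe + 4.0, h)
    h = h * (255.0 / 6.0)

    s = np.where(mx > 0, delta / np.where(mx > 0, mx, 1.0) * 255.0, 0.0)
    return np.column_stack([h, s, mx])


def rgb_to_hsb(r: float, g: float, b: float) -> tuple[float, float, float]:
    """Convert one RGB triplet (each 0-255) to HSB, all outputs 0-255.

    Gray inputs (max == min) return hue 0 and saturation 0; black returns
    saturation 0.

    Raises
    ------
    DomainError
        If any component lies outside [0, 255].
    """
    triplet = np.asarray([r, g, b], dtype=float)
    if np.any(triplet < 0) or np.any(triplet > 255) or not np.all(np.isfinite(triplet)):
        raise DomainError(f"RGB components must lie in [0, 255], got {(r, g, b)}")
    h, s, br = _hsb_pixels(triplet.reshape(1, 3))[0]
    return float(h), float(s), float(br)


@dataclass(frozen=True)
class ChannelStats:
    """Per-ROI channel means (0-255 scale) and pixel accounting.

    ``rgb_mean`` is the arithmetic mean of the red/green/blue means; the HSB
    means are averages of per-pixel HSB values.  Statistics cover exactly
    ``n_pixels_total - n_pixels_masked`` pixels.
    """

    red_mean: float
    green_mean: float
    blue_mean: float
    rgb_mean: float
    hue_mean: float
    saturation_mean: float
    brightness_mean: float
    n_pixels_total: int
    n_pixels_masked: int

    def signal(self, channel: str) -> float:
        """Return the mean of the requested channel (one of CHANNELS)."""
        if channel not in CHANNELS:
            raise DomainError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
        if channel == "rgb_mean":
            return self.rgb_mean
        return getattr(self, f"{channel}_mean")

    def as_dict(self) -> dict:
        return asdict(self)


def roi_channel_stats(pixels, mask=None) -> ChannelStats:
    """Compute ChannelStats over the unmasked pixels of an ROI.

    Parameters
    ----------
    pixels : array-like, shape (N, 3)
        RGB triplets, 0-255 (fractional values allowed).
    mask : bool array-like, shape (N,), optional
        True marks a pixel as masked (excluded).  Default: nothing masked.

    Raises
    ------
    DegenerateROIError
        If fewer than MIN_ROI_PIXELS unmasked pixels remain — the well is
        unusable and must be excluded downstream.
    DomainError
        If any pixel value lies outside [0, 255].
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3:
        raise DomainError(f"expected (N, 3) pixel array, got shape {px.shape}")
    if px.size and (px.min() < 0 or px.max() > 255):
        raise DomainError("pixel values must lie in [0, 255]")
    n_total = px.shape[0]
    if mask is None:
        mask = np.zeros(n_total, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n_total,):
            raise DomainError("mask must be a boolean vector matching the pixel count")
    kept = px[~mask]
    if kept.shape[0] < MIN_ROI_PIXELS:
        raise DegenerateROIError(
            f"only {kept.shape[0]} unmasked pixels (< {MIN_ROI_PIXELS}); ROI unusable"
        )
    r_mean, g_mean, b_mean = kept.mean(axis=0)
    hsb = _hsb_pixels(kept)
    h_mean, s_mean, br_mean = hsb.mean(axis=0)
    return ChannelStats(
        red_mean=float(r_mean),
        green_mean=float(g_mean),
        blue_mean=float(b_mean),
        rgb_mean=float((r_mean + g_mean + b_mean) / 3.0),
        hue_mean=float(h_mean),
        saturation_mean=float(s_mean),
        brightness_mean=float(br_mean),
        n_pixels_total=int(n_total),
        n_pixels_masked=int(mask.sum()),
    )
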