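"""In-matrix calibration of channel signal against analyte concentration.

Standards prepared in the same formulation matrix as the unknowns are
photographed together with them; the channel signal y is regressed on
nominal concentration x (% w/w) by ordinary least squares.  Because the
color response loses proportionality at low analyte levels (the oxidant is
no longer limiting), the usable calibration is restricted to a linear
dynamic range determined by an explicit acceptance rule: the fit must reach
a minimum R^2 and every retained standard must back-calculate within a bias
limit, endpoints being trimmed (low end first) until both hold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as _sstats

from .colorimetry import ANALYTICAL_CHANNELS
from .errors import (
    ChannelSelectionError,
    DegenerateCurveError,
    DegenerateFitError,
    InsufficientDataError,
)
from .errors import NoLinearRangeError

#: Default R^2 acceptance threshold for a calibration line.
DEFAULT_R2_MIN = 0.98

#: Default per-standard back-calculation bias acceptance, percent.
DEFAULT_BACKCALC_BIAS_MAX = 15.0


class LineFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


def fit_line(points: Sequence[tuple[float, float]]) -> LineFit:
    """Ordinary least squares y = intercept + slope * x.

    R^2 is computed as 1 - SSE/SST.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 points or fewer than 2 distinct x values.
    DegenerateFitError
        All y identical (SST = 0): no signal variance to explain.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InsufficientDataError(f"expected (n, 2) points, got shape {pts.shape}")
    if pts.shape[0] < 3:
        raise InsufficientDataError(f"need >= 3 points, got {pts.shape[0]}")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise InsufficientDataError("need >= 2 distinct x values")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise DegenerateFitError("all y identical (SST = 0)")
    res = _sstats.linregress(x, y)
    pred = res.intercept + res.slope * x
    sse = float(((y - pred) ** 2).sum())
    return LineFit(float(res.slope), float(res.intercept), 1.0 - sse / sst)


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted calibration line for one channel in one matrix.

    ``points`` are the (concentration % w/w, signal) pairs actually retained
    by the fit; ``linear_range`` is (c_lo, c_hi) over those points.
    """

    channel: str
    slope: float
    intercept: float
    r_squared: float
    linear_range: tuple[float, float]
    matrix: str = ""
    points: tuple = field(default_factory=tuple)

    def __post_init__(self):
        c_lo, c_hi = self.linear_range
        if not c_lo < c_hi:
            raise DegenerateCurveError(f"degenerate linear range {self.linear_range}")

    def predict_signal(self, conc: float) -> float:
        return self.intercept + self.slope * conc

    @property
    def span(self) -> float:
        return self.linear_range[1] - self.linear_range[0]

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "linear_range": list(self.linear_range),
            "matrix": self.matrix,
            "points": [list(p) for p in self.points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            channel=d["channel"],
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            linear_range=tuple(d["linear_range"]),
            matrix=d.get("matrix", ""),
            points=tuple(tuple(p) for p in d.get("points", ())),
        )


class BackCalcResult(NamedTuple):
    conc: float
    out_of_range: bool


def back_calculate(
    curve: CalibrationCurve, signal: float, range_tolerance: float = 0.10
) -> BackCalcResult:
    """Invert the calibration line: c = (signal - intercept) / slope.

    The result is flagged out-of-range when it falls outside the linear
    range extended by a tolerance band: ``range_tolerance`` of the range
    width above the top, but only ``range_tolerance`` of the lower limit
    itself below the floor.  The asymmetry is deliberate — the response is
    known to lose proportionality below the lower limit, so back-calculated
    values may not dip more than fractionally below it, while mild
    excursions above the top merely extrapolate a still-linear response.

    Raises
    ------
    DegenerateCurveError
        If the curve slope is zero.
    """
    if curve.slope == 0:
        raise DegenerateCurveError("calibration slope is zero; cannot back-calculate")
    conc = (signal - curve.intercept) / curve.slope
    c_lo, c_hi = curve.linear_range
    lo_bound = c_lo * (1.0 - range_tolerance)
    hi_bound = c_hi + range_tolerance * (c_hi - c_lo)
    out = not (lo_bound <= conc <= hi_bound)
    return BackCalcResult(float(conc), out)


def _backcalc_biases(pts: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Percent bias of each standard's back-calculated concentration."""
    if slope == 0:
        return np.full(pts.shape[0], np.inf)
    back = (pts[:, 1] - intercept) / slope
    nominal = pts[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        bias = 100.0 * (back - nominal) / nominal
    bias[~np.isfinite(bias)] = np.inf
    return bias


def determine_linear_range(
    standards: Sequence[tuple[float, float]],
    r2_min: float = DEFAULT_R2_MIN,
    backcalc_bias_max: float = DEFAULT_BACKCALC_BIAS_MAX,
    *,
    channel: str = "blue",
    matrix: str = "",
) -> CalibrationCurve:
    """Fit standards and trim endpoints until linearity criteria pass.

    Starting from all standards (sorted by concentration), repeatedly fit,
    back-calculate every standard, and test both criteria: R^2 >= r2_min
    and every |back-calc bias| <= backcalc_bias_max percent.  On failure,
    drop the standards at the lowest retained concentration if that
    endpoint violates the bias limit (low-concentration clipping is the
    dominant failure mode); otherwise drop the highest.  Stop when both
    criteria pass, or fail once fewer than 3 standards remain.

    Replicate standards at one concentration are individual fit points and
    are dropped together when their concentration is trimmed.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 standards or fewer than 3 distinct concentrations.
    NoLinearRangeError
        No passing subset of >= 3 standards exists.
    """
    pts = np.asarray(sorted((float(x), float(y)) for x, y in standards), dtype=float)
    if pts.shape[0] < 4 or np.unique(pts[:, 0]).size < 3:
        raise InsufficientDataError(
            "need >= 4 standards spanning >= 3 distinct concentrations"
        )
    while pts.shape[0] >= 3 and np.unique(pts[:, 0]).size >= 2:
        try:
            fit = fit_line(pts)
        except (DegenerateFitError, InsufficientDataError) as exc:
            raise NoLinearRangeError(f"no linear range: {exc}") from exc
        biases = _backcalc_biases(pts, fit.slope, fit.intercept)
        if fit.r_squared >= r2_min and np.all(np.abs(biases) <= backcalc_bias_max):
            c_lo, c_hi = float(pts[0, 0]), float(pts[-1, 0])
            return CalibrationCurve(
                channel=channel,
                slope=fit.slope,
                intercept=fit.intercept,
                r_squared=fit.r_squared,
                linear_range=(c_lo, c_hi),
                matrix=matrix,
                points=tuple(map(tuple, pts)),
            )
        lo_conc = pts[0, 0]
        lo_idx = pts[:, 0] == lo_conc
        if np.any(np.abs(biases[lo_idx]) > backcalc_bias_max):
            pts = pts[~lo_idx]
        else:
            pts = pts[pts[:, 0] != pts[-1, 0]]
    raise NoLinearRangeError(
        f"no subset of >= 3 standards meets r2 >= {r2_min} and "
        f"|bias| <= {backcalc_bias_max}%"
    )


def select_channel(
    curves: dict[str, CalibrationCurve] | Sequence[CalibrationCurve],
    r2_min: float = DEFAULT_R2_MIN,
) -> str:
    """Pick the analytical channel: best sensitivity among the widest-range fits.

    Hue is excluded a priori (no linear concentration dependence).  Among
    candidates with R^2 >= r2_min, those whose linear range span equals the
    widest available span are kept, and the one with the largest |slope| —
    i.e. the most sensitive — is returned.

    Raises
    ------
    ChannelSelectionError
        If no candidate passes.
    """
    if isinstance(curves, dict):
        candidates = list(curves.values())
    else:
        candidates = list(curves)
    candidates = [
        c for c in candidates if c.channel in ANALYTICAL_CHANNELS and c.r_squared >= r2_min
    ]
    if not candidates:
        raise ChannelSelectionError(f"no channel reaches r_squared >= {r2_min}")
    widest = max(c.span for c in candidates)
    finalists = [c for c in candidates if c.span >= widest - 1e-9]
    best = max(finalists, key=lambda c: abs(c.slope))
    return best.channel


def curves_to_json(curves: dict[str, CalibrationCurve], path) -> None:
    with open(path, "w") as fh:
        json.dump({ch: c.to_dict() for ch, c in curves.items()}, fh, indent=2)


def curves_from_json(path) -> dict[str, CalibrationCurve]:
    with open(path) as fh:
        raw = json.load(fh)
    return {ch: CalibrationCurve.from_dict(d) for ch, d in raw.items()}
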