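"""Quantification of unknowns: direct calibration and standard addition.

Direct quantification back-calculates the (replicate-averaged) signal of an
unknown through a same-photo calibration curve.

Standard addition handles matrices whose background distorts the response:
aliquots of the unknown are spiked with known analyte increments and the
fitted addition line y = a + b*x is extrapolated.  Classically one
extrapolates to the zero-analyte signal, but when the response is nonlinear
below some concentration floor (here ~2.5 % w/w) that extrapolation leaves
the validated range.  The modified estimator instead extrapolates to the
signal of a nonzero in-matrix reference standard at c_ref:

    c0 = c_ref + (a - y_ref) / b

Under a shared linear response y = alpha + beta*(c0 + x), y_ref = alpha +
beta*c_ref and b = beta, so the formula is exact for either sign of b, and
with c_ref = 0, y_ref = alpha it reduces to the classical intercept
extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .calibration import (
    DEFAULT_R2_MIN,
    CalibrationCurve,
    back_calculate,
    fit_line,
)
from .errors import DegenerateFitError, DomainError, InsufficientDataError

FLAG_OUT_OF_RANGE = "out-of-range"
FLAG_EXTRAPOLATION = "extrapolation-distance"
FLAG_LOW_R2 = "low-r2"


@dataclass(frozen=True)
class QuantResult:
    """An estimated concentration with its method and diagnostics."""

    estimate: float  # c0, % w/w
    method: str  # "direct" | "standard_addition"
    channel: str
    r_squared: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def out_of_range(self) -> bool:
        return FLAG_OUT_OF_RANGE in self.flags


def quantify_direct(
    curve: CalibrationCurve, signals: float | Iterable[float], channel: str | None = None
) -> QuantResult:
    """Back-calculate an unknown from one signal or a replicate set.

    Replicate signals are averaged before inversion; the curve's
    out-of-range flag propagates to the result.
    """
    arr = np.atleast_1d(np.asarray(signals, dtype=float))
    if arr.size == 0:
        raise InsufficientDataError("no signals supplied")
    mean_signal = float(arr.mean())
    conc, out = back_calculate(curve, mean_signal)
    flags = (FLAG_OUT_OF_RANGE,) if out else ()
    return QuantResult(
        estimate=conc,
        method="direct",
        channel=channel or curve.channel,
        r_squared=curve.r_squared,
        flags=flags,
    )


@dataclass(frozen=True)
class StandardAdditionDesign:
    """Spiked-aliquot signals plus a nonzero in-matrix reference standard.

    ``additions`` holds (added concentration x_i % w/w, signal y_i) for
    aliquots of the unknown; an unspiked x=0 aliquot is allowed.  The
    reference standard (c_ref, y_ref) must be measured in the same photo
    and must sit inside the matrix's linear range.
    """

    additions: tuple  # of (x, y) pairs
    ref_conc: float
    ref_signal: float
    channel: str = "blue"
    matrix: str = ""

    def __post_init__(self):
        adds = tuple((float(x), float(y)) for x, y in self.additions)
        object.__setattr__(self, "additions", adds)
        if len(adds) < 3:
            raise InsufficientDataError("standard addition needs >= 3 aliquots")
        xs = {x for x, _ in adds}
        if len(xs) < 2:
            raise InsufficientDataError("standard addition needs >= 2 distinct added levels")
        sigs = [y for _, y in adds] + [self.ref_signal]
        if any(not (0.0 <= s <= 255.0) for s in sigs):
            raise DomainError("signals must lie in [0, 255]")
        if self.ref_conc <= 0:
            raise DomainError("reference standard concentration must be positive")


def quantify_standard_addition(
    design: StandardAdditionDesign,
    linear_range: tuple[float, float] | None = None,
    r2_min: float = DEFAULT_R2_MIN,
) -> QuantResult:
    """Estimate c0 by extrapolating the addition line to the reference signal.

    Fits y = a + b*x over all aliquots by OLS and returns
    c0 = c_ref + (a - y_ref)/b.  Flags are set when the addition fit's R^2
    falls below ``r2_min`` or — when ``linear_range`` is supplied — when c0
    or c0 + max(x_i) falls outside it (the estimate then leans on
    out-of-range extrapolation).

    Raises
    ------
    DegenerateFitError
        If the fitted slope b is zero.
    """
    fit = fit_line(design.additions)
    if fit.slope == 0:
        raise DegenerateFitError("addition line has zero slope")
    c0 = design.ref_conc + (fit.intercept - design.ref_signal) / fit.slope

    flags: list[str] = []
    if fit.r_squared < r2_min:
        flags.append(FLAG_LOW_R2)
    if linear_range is not None:
        c_lo, c_hi = linear_range
        max_added = max(x for x, _ in design.additions)
        if not (c_lo <= c0 <= c_hi):
            flags.append(FLAG_OUT_OF_RANGE)
        if c0 + max_added > c_hi or c0 < c_lo:
            flags.append(FLAG_EXTRAPOLATION)
    return QuantResult(
        estimate=float(c0),
        method="standard_addition",
        channel=design.channel,
        r_squared=fit.r_squared,
        flags=tuple(dict.fromkeys(flags)),
    )


def bias_percent(measured: float, nominal: float) -> float:
    """Percent bias 100*(measured - nominal)/nominal.

    Raises
    ------
    DomainError
        If nominal <= 0.
    """
    if nominal <= 0:
        raise DomainError(f"nominal concentration must be positive, got {nominal}")
    return 100.0 * (measured - nominal) / nominal
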