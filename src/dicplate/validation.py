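"""Method-validation statistics: intermediate precision, accuracy, linearity.

Intermediate precision is the coefficient of variation (CV%) of replicate
estimates of a QC level obtained under varied conditions (separate photos,
each with its own in-photo calibration).  Accuracy is the percent bias of
the mean measured concentration against nominal.  Linearity is summarized
per run by the calibration R^2 and linear range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve
from .errors import ConfigurationError, DomainError, InsufficientDataError
from .quantification import bias_percent


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 * sample SD (n-1) / mean.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 values.
    DomainError
        Non-positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("CV needs >= 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"CV undefined for non-positive mean {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


@dataclass(frozen=True)
class LevelSummary:
    nominal_conc: float
    n: int
    mean_measured: float
    cv_percent: float
    bias_percent: float


@dataclass(frozen=True)
class RunResult:
    """One run's same-photo calibration plus its QC estimates.

    ``estimates`` holds (nominal concentration % w/w, measured % w/w) pairs.
    """

    run_id: str
    curve: CalibrationCurve | None
    estimates: tuple  # of (nominal, measured)


@dataclass(frozen=True)
class ValidationReport:
    per_level: tuple  # of LevelSummary
    linearity: tuple  # of (run_id, r_squared, linear_range)
    max_abs_bias: float
    max_cv: float
    min_r_squared: float

    def to_dict(self) -> dict:
        return {
            "per_level": [vars(lv) | {} for lv in self.per_level],
            "linearity": [
                {"run_id": rid, "r_squared": r2, "linear_range": list(rng)}
                for rid, r2, rng in self.linearity
            ],
            "overall": {
                "max_abs_bias": self.max_abs_bias,
                "max_cv": self.max_cv,
                "min_r_squared": self.min_r_squared,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one row per QC level, validation-report style."""
        return pd.DataFrame(
            [
                {
                    "nominal_conc": lv.nominal_conc,
                    "cv_percent": lv.cv_percent,
                    "n": lv.n,
                    "mean_measured": lv.mean_measured,
                    "bias_percent": lv.bias_percent,
                }
                for lv in self.per_level
            ]
        )


def build_validation_report(runs: Sequence[RunResult]) -> ValidationReport:
    """Aggregate per-run QC estimates into a validation report.

    Every level must carry >= 2 replicate estimates; per-level bias is the
    bias of the mean estimate against nominal (a validation table pairs one
    measured value with n replicates).

    Raises
    ------
    ConfigurationError
        If a run lacks its same-photo calibration.
    InsufficientDataError
        If any level has fewer than 2 replicates.
    """
    for run in runs:
        if run.curve is None:
            raise ConfigurationError(f"run {run.run_id} is missing its calibration")

    by_level: dict[float, list[float]] = {}
    for run in runs:
        for nominal, measured in run.estimates:
            by_level.setdefault(float(nominal), []).append(float(measured))

    levels = []
    for nominal in sorted(by_level):
        measured = by_level[nominal]
        if len(measured) < 2:
            raise InsufficientDataError(
                f"level {nominal} has {len(measured)} replicate(s); need >= 2"
            )
        mean_measured = float(np.mean(measured))
        levels.append(
            LevelSummary(
                nominal_conc=nominal,
                n=len(measured),
                mean_measured=mean_measured,
                cv_percent=cv_percent(measured),
                bias_percent=bias_percent(mean_measured, nominal),
            )
        )
    linearity = tuple(
        (run.run_id, run.curve.r_squared, run.curve.linear_range) for run in runs
    )
    return ValidationReport(
        per_level=tuple(levels),
        linearity=linearity,
        max_abs_bias=max(abs(lv.bias_percent) for lv in levels),
        max_cv=max(lv.cv_percent for lv in levels),
        min_r_squared=min(r2 for _, r2, _ in linearity),
    )
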