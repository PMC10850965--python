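"""End-to-end orchestration: photo -> observations -> calibration -> results.

The unit of analysis is one photo that contains both the calibration
standards and the unknowns (same-photo calibration is what cancels shared
illumination changes between photos).  Calibration is always per matrix:
standards only ever calibrate wells of their own matrix label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .calibration import CalibrationCurve, determine_linear_range, select_channel
from .colorimetry import ANALYTICAL_CHANNELS
from .config import RunConfig, config_from_dict
from .errors import ConfigurationError, DicplateError, NoLinearRangeError
from .plate_reader import (
    GridSpec,
    PlateImage,
    WellObservation,
    load_image,
    load_plate_map,
    locate_wells,
    observations_to_frame,
    read_plate,
)
from .quantification import (
    QuantResult,
    StandardAdditionDesign,
    quantify_direct,
    quantify_standard_addition,
)
from .synthetic_plate import SimulatedRun
from .validation import RunResult, ValidationReport, build_validation_report

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("sample_id", "matrix", "method", "channel", "estimate",
                  "nominal_conc", "flags", "r2")


@dataclass
class PlateAnalysis:
    """Everything one photo yields: observations, curves, quantified results."""

    observations: list
    curves: dict  # matrix -> {channel: CalibrationCurve}
    selected_channel: dict  # matrix -> channel name
    results: pd.DataFrame

    def curve(self, matrix: str, channel: str | None = None) -> CalibrationCurve:
        channel = channel or self.selected_channel[matrix]
        return self.curves[matrix][channel]

    def observations_frame(self) -> pd.DataFrame:
        return observations_to_frame(self.observations)


def _calibrate_matrix(
    standards: list, channel: str, r2_min: float, backcalc_bias_max: float, matrix: str
) -> tuple[dict, str]:
    """Fit calibration curve(s) for one matrix; resolve 'auto' channel."""
    channels = list(ANALYTICAL_CHANNELS) if channel == "auto" else [channel]
    curves = {}
    for ch in channels:
        points = [(obs.nominal_conc, obs.signal(ch)) for obs in standards]
        try:
            curves[ch] = determine_linear_range(
                points, r2_min=r2_min, backcalc_bias_max=backcalc_bias_max,
                channel=ch, matrix=matrix,
            )
        except DicplateError as exc:
            if channel != "auto":
                raise
            logger.info("matrix %s channel %s rejected: %s", matrix, ch, exc)
    if not curves:
        raise NoLinearRangeError(f"no channel calibrates in matrix {matrix!r}")
    chosen = select_channel(curves, r2_min=r2_min) if channel == "auto" else channel
    return curves, chosen


def analyze_plate(
    image: PlateImage,
    plate_map: pd.DataFrame,
    grid: GridSpec,
    config: RunConfig | None = None,
) -> PlateAnalysis:
    """Run the full pipeline on one photo.

    Standards calibrate their own matrix; QC wells are quantified directly
    (replicates at one nominal level averaged first), sample wells
    individually, and spiked_sample + reference_standard wells through the
    modified standard-addition estimator.
    """
    config = config or RunConfig()
    layout = locate_wells(image, grid)
    observations = read_plate(
        image, layout, plate_map,
        k_mad=config.mask_k_mad,
        glare_min=config.mask_glare_min,
        reject_fraction=config.mask_reject_fraction,
    )
    valid = [o for o in observations if o.valid]

    matrices = sorted({o.matrix for o in valid})
    curves: dict = {}
    selected: dict = {}
    for matrix in matrices:
        standards = [
            o for o in valid
            if o.matrix == matrix and o.role == "standard" and o.nominal_conc is not None
        ]
        if not standards:
            continue
        curves[matrix], selected[matrix] = _calibrate_matrix(
            standards, config.channel, config.r2_min, config.backcalc_bias_max, matrix
        )

    needs_curve = [o for o in valid if o.role in ("qc", "sample", "spiked_sample")]
    if needs_curve and not curves:
        raise ConfigurationError("no calibration standards available on this plate")

    rows = []

    def record(sample_id: str, matrix: str, result: QuantResult, nominal=None):
        rows.append({
            "sample_id": sample_id,
            "matrix": matrix,
            "method": result.method,
            "channel": result.channel,
            "estimate": result.estimate,
            "nominal_conc": nominal,
            "flags": ";".join(result.flags),
            "r2": result.r_squared,
        })

    for matrix in matrices:
        if matrix not in curves:
            orphans = [o for o in needs_curve if o.matrix == matrix]
            if orphans:
                raise ConfigurationError(
                    f"wells {[o.well_id for o in orphans]} in matrix {matrix!r} "
                    "have no same-photo standards"
                )
            continue
        channel = selected[matrix]
        curve = curves[matrix][channel]

        qc = [o for o in valid if o.matrix == matrix and o.role == "qc"]
        for nominal in sorted({o.nominal_conc for o in qc}):
            replicates = [o for o in qc if o.nominal_conc == nominal]
            result = quantify_direct(curve, [o.signal(channel) for o in replicates])
            record(f"{matrix}:qc:{nominal:g}", matrix, result, nominal)

        for obs in (o for o in valid if o.matrix == matrix and o.role == "sample"):
            record(obs.well_id, matrix, quantify_direct(curve, obs.signal(channel)))

        spiked = [o for o in valid if o.matrix == matrix and o.role == "spiked_sample"]
        refs = [o for o in valid if o.matrix == matrix and o.role == "reference_standard"]
        if spiked:
            if not refs:
                raise ConfigurationError(
                    f"spiked samples in matrix {matrix!r} lack a reference standard"
                )
            ref_concs = {o.nominal_conc for o in refs}
            if len(ref_concs) != 1:
                raise ConfigurationError(
                    f"reference standards in matrix {matrix!r} disagree on concentration"
                )
            design = StandardAdditionDesign(
                additions=tuple(
                    (o.added_conc if o.added_conc is not None else 0.0, o.signal(channel))
                    for o in spiked
                ),
                ref_conc=ref_concs.pop(),
                ref_signal=float(pd.Series([o.signal(channel) for o in refs]).mean()),
                channel=channel,
                matrix=matrix,
            )
            result = quantify_standard_addition(
                design, linear_range=curve.linear_range, r2_min=config.r2_min
            )
            record(f"{matrix}:standard_addition", matrix, result)

    return PlateAnalysis(
        observations=observations,
        curves=curves,
        selected_channel=selected,
        results=pd.DataFrame(rows, columns=list(RESULT_COLUMNS)),
    )


def analyze_simulated_run(run: SimulatedRun, config: RunConfig | None = None) -> PlateAnalysis:
    return analyze_plate(run.image, run.plate_map, run.grid, config)


def _grid_from_layout_yaml(path) -> GridSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw).grid_spec()


def analyze_run_dir(run_dir, config: RunConfig | None = None) -> PlateAnalysis:
    """Analyze an on-disk run directory (plate.png, plate_map.csv[, layout.yaml])."""
    run_dir = Path(run_dir)
    config = config or RunConfig()
    image = load_image(run_dir / "plate.png")
    plate_map = load_plate_map(run_dir / "plate_map.csv")
    layout_path = run_dir / "layout.yaml"
    grid = _grid_from_layout_yaml(layout_path) if layout_path.exists() else config.grid_spec()
    return analyze_plate(image, plate_map, grid, config)


def run_result_from_analysis(run_id: str, analysis: PlateAnalysis) -> RunResult:
    """Condense one photo's analysis into a validation RunResult."""
    qc = analysis.results[analysis.results["method"] == "direct"]
    qc = qc[qc["nominal_conc"].notna()]
    estimates = tuple(
        (float(r["nominal_conc"]), float(r["estimate"])) for _, r in qc.iterrows()
    )
    matrices = sorted(analysis.curves)
    curve = analysis.curve(matrices[0]) if matrices else None
    return RunResult(run_id=run_id, curve=curve, estimates=estimates)


def validate_runs(runs_analyses: list[tuple[str, PlateAnalysis]]) -> ValidationReport:
    return build_validation_report(
        [run_result_from_analysis(rid, a) for rid, a in runs_analyses]
    )


def validate_study_dir(study_dir, config: RunConfig | None = None) -> ValidationReport:
    """Analyze every run of a study directory and build the validation report."""
    study_dir = Path(study_dir)
    index_path = study_dir / "study.json"
    if not index_path.exists():
        raise ConfigurationError(f"{study_dir} has no study.json index")
    with open(index_path) as fh:
        index = json.load(fh)
    run_ids = index.get("runs", [])
    if len(run_ids) < 2:
        raise ConfigurationError("intermediate precision needs >= 2 runs")
    missing = [rid for rid in run_ids if not (study_dir / rid / "plate.png").exists()]
    if missing:
        raise ConfigurationError(f"study incomplete; missing runs: {missing}")
    analyses = [(rid, analyze_run_dir(study_dir / rid, config)) for rid in run_ids]
    return validate_runs(analyses)
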