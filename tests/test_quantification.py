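"""Direct and standard-addition quantification, bias arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

import dicplate as dp
from dicplate.errors import DegenerateFitError, DomainError, InsufficientDataError
from dicplate.quantification import FLAG_OUT_OF_RANGE


@pytest.fixture
def blue_curve():
    return dp.CalibrationCurve("blue", -3.009, 128.19, 0.992, (2.5, 30.0))


def test_direct_replicates_average_first(blue_curve):
    res = dp.quantify_direct(blue_curve, [98.0, 98.2])
    assert res.estimate == pytest.approx((128.19 - 98.1) / 3.009)
    assert res.estimate == pytest.approx(10.0, abs=1e-3)
    assert res.method == "direct"
    assert not res.out_of_range


def test_direct_signal_on_curve_returns_backcalc(blue_curve):
    sig = blue_curve.predict_signal(18.13)
    res = dp.quantify_direct(blue_curve, sig)
    assert res.estimate == pytest.approx(18.13, abs=1e-9)


def test_direct_far_outside_range_flagged(blue_curve):
    sig = blue_curve.predict_signal(45.0)  # maps to 45 % w/w on a 2.5-30 range
    res = dp.quantify_direct(blue_curve, sig)
    assert res.out_of_range


def test_standard_addition_constructed_exact_case():
    # additions on y = 100 - 3x (alpha=130, beta=-3, true c0=10)
    design = dp.StandardAdditionDesign(
        additions=[(0, 100.0), (5, 85.0), (10, 70.0), (15, 55.0)],
        ref_conc=5.0,
        ref_signal=115.0,
    )
    res = dp.quantify_standard_addition(design)
    assert res.estimate == pytest.approx(10.0, abs=1e-9)
    assert res.method == "standard_addition"


def test_standard_addition_saturation_style_line():
    # saturation-like response 4.185x + 79.49; unknown at 8, reference at 10
    adds = [(x, 112.97 + 4.185 * x) for x in (0, 4, 8, 12)]
    design = dp.StandardAdditionDesign(additions=adds, ref_conc=10.0, ref_signal=121.34)
    res = dp.quantify_standard_addition(design)
    assert res.estimate == pytest.approx(8.0, abs=1e-9)


@given(
    beta=st.one_of(
        st.floats(min_value=-6.0, max_value=-0.5),
        st.floats(min_value=0.5, max_value=6.0),
    ),
    alpha=st.floats(min_value=60.0, max_value=160.0),
    c0=st.floats(min_value=3.0, max_value=15.0),
    c_ref=st.floats(min_value=2.6, max_value=15.0),
)
@settings(max_examples=80, deadline=None)
def test_standard_addition_exact_on_shared_linear_response(beta, alpha, c0, c_ref):
    """Exact for any slope sign when everything follows one linear response."""
    xs = (0.0, 3.0, 6.0, 9.0)
    sigs = [alpha + beta * (c0 + x) for x in xs]
    ref_sig = alpha + beta * c_ref
    if not all(0 <= s <= 255 for s in sigs + [ref_sig]):
        return
    design = dp.StandardAdditionDesign(
        additions=list(zip(xs, sigs)), ref_conc=c_ref, ref_signal=ref_sig
    )
    res = dp.quantify_standard_addition(design)
    assert res.estimate == pytest.approx(c0, abs=1e-9)


def test_standard_addition_reduces_to_classical_at_zero_reference():
    """c_ref -> 0, y_ref -> alpha recovers the classical intercept extrapolation.

    The design type requires a positive reference, so the reduction is
    checked by direct formula comparison at a vanishing reference level.
    """
    alpha, beta, c0 = 120.0, -2.5, 9.0
    xs = (0.0, 5.0, 10.0)
    adds = [(x, alpha + beta * (c0 + x)) for x in xs]
    fit = dp.fit_line(adds)
    classical = (fit.intercept - alpha) / fit.slope  # brute-force classical estimator
    eps = 1e-9
    design = dp.StandardAdditionDesign(
        additions=adds, ref_conc=eps, ref_signal=alpha + beta * eps
    )
    res = dp.quantify_standard_addition(design)
    assert classical == pytest.approx(c0, abs=1e-6)
    assert res.estimate == pytest.approx(classical, abs=1e-6)


def test_standard_addition_low_estimate_is_flagged():
    alpha, beta, c0 = 120.0, -3.0, 1.0  # below a 2.5 lower limit
    adds = [(x, alpha + beta * (c0 + x)) for x in (0.0, 5.0, 10.0)]
    design = dp.StandardAdditionDesign(additions=adds, ref_conc=5.0, ref_signal=alpha + beta * 5.0)
    res = dp.quantify_standard_addition(design, linear_range=(2.5, 30.0))
    assert FLAG_OUT_OF_RANGE in res.flags


def test_standard_addition_design_validation():
    with pytest.raises(InsufficientDataError):
        dp.StandardAdditionDesign(additions=[(0, 100), (5, 90)], ref_conc=5, ref_signal=95)
    with pytest.raises(InsufficientDataError):
        dp.StandardAdditionDesign(
            additions=[(5, 90), (5, 91), (5, 92)], ref_conc=5, ref_signal=95
        )
    with pytest.raises(DomainError):
        dp.StandardAdditionDesign(
            additions=[(0, 300), (5, 90), (10, 80)], ref_conc=5, ref_signal=95
        )


def test_standard_addition_zero_slope_errors():
    design = dp.StandardAdditionDesign(
        additions=[(0, 90.0), (5, 90.0), (10, 90.0), (15, 90.0)],
        ref_conc=5.0,
        ref_signal=90.0,
    )
    with pytest.raises(DegenerateFitError):
        dp.quantify_standard_addition(design)


def test_simulated_standard_addition_recovers_unknown(default_model):
    """Full-noise simulated addition series: estimate within the documented
    worst-case quantification bias of ~11%."""
    import dicplate.pipeline as pl
    import pandas as pd

    true_c0 = 10.0
    entries = [
        ("S01", "spiked_sample", "cream_b", true_c0, 0.0),
        ("S02", "spiked_sample", "cream_b", true_c0, 5.0),
        ("S03", "spiked_sample", "cream_b", true_c0, 10.0),
        ("S04", "spiked_sample", "cream_b", true_c0, 15.0),
        ("R01", "reference_standard", "cream_b", 10.0, None),
    ] + [
        (f"C{i}", "standard", "cream_b", c, None)
        for i, c in enumerate((2.52, 6.03, 10.07, 18.13, 23.32, 27.21, 30.03))
    ]
    pm = pd.DataFrame(
        entries, columns=["well_id", "role", "matrix", "nominal_conc", "added_conc"]
    )
    grid = dp.strip_grid(len(pm))
    image, _ = dp.render_plate(default_model, pm, grid, seed=21)
    analysis = pl.analyze_plate(image, pm, grid)
    row = analysis.results[analysis.results["method"] == "standard_addition"].iloc[0]
    assert abs(dp.bias_percent(row["estimate"], true_c0)) <= 10.91


def test_direct_and_standard_addition_agree_on_simulated_run(default_model):
    import dicplate.pipeline as pl
    import pandas as pd

    true_c0 = 12.0
    entries = [
        ("S01", "spiked_sample", "cream_b", true_c0, 0.0),
        ("S02", "spiked_sample", "cream_b", true_c0, 5.0),
        ("S03", "spiked_sample", "cream_b", true_c0, 10.0),
        ("Q01", "sample", "cream_b", true_c0, None),
        ("R01", "reference_standard", "cream_b", 10.0, None),
    ] + [
        (f"C{i}", "standard", "cream_b", c, None)
        for i, c in enumerate((2.52, 6.03, 10.07, 18.13, 23.32, 27.21, 30.03))
    ]
    pm = pd.DataFrame(
        entries, columns=["well_id", "role", "matrix", "nominal_conc", "added_conc"]
    )
    grid = dp.strip_grid(len(pm))
    image, _ = dp.render_plate(default_model, pm, grid, seed=8)
    analysis = pl.analyze_plate(image, pm, grid)
    direct = analysis.results[analysis.results["method"] == "direct"].iloc[0]["estimate"]
    sa = analysis.results[analysis.results["method"] == "standard_addition"].iloc[0]["estimate"]
    assert direct == pytest.approx(sa, abs=2.0)  # combined fit noise at default settings


def test_bias_percent_values():
    assert dp.bias_percent(6.03, 6.03) == 0.0
    assert dp.bias_percent(11.09, 10.0) == pytest.approx(10.90, abs=1e-9)
    assert dp.bias_percent(2.26, 2.50) == pytest.approx(-9.60, abs=1e-9)


def test_bias_percent_rejects_nonpositive_nominal():
    with pytest.raises(DomainError):
        dp.bias_percent(5.0, 0.0)
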