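"""Calibration fits, back-calculation, linear-range trimming, channel choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dicplate as dp
from dicplate.errors import (
    ChannelSelectionError,
    DegenerateCurveError,
    DegenerateFitError,
    InsufficientDataError,
    NoLinearRangeError,
)


def brute_force_ols(points):
    """Independent closed-form normal-equations solution."""
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    n = len(x)
    sxx = (x**2).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    sse = ((y - intercept - slope * x) ** 2).sum()
    sst = ((y - y.mean()) ** 2).sum()
    return slope, intercept, 1 - sse / sst


def test_fit_line_exact_line():
    fit = dp.fit_line([(1, 3), (2, 5), (3, 7)])
    assert fit.slope == pytest.approx(2)
    assert fit.intercept == pytest.approx(1)
    assert fit.r_squared == pytest.approx(1)


def test_fit_line_hand_computed_case():
    # SSE = 1/6, SST = 14/3 -> r^2 = 27/28
    fit = dp.fit_line([(0, 1), (1, 2), (2, 4)])
    assert fit.slope == pytest.approx(1.5)
    assert fit.intercept == pytest.approx(5 / 6)
    assert fit.r_squared == pytest.approx(27 / 28)


@given(
    st.lists(
        st.tuples(
            st.floats(min_value=-50, max_value=50),
            st.floats(min_value=-100, max_value=100),
        ),
        min_size=3,
        max_size=12,
    )
)
@settings(max_examples=60, deadline=None)
def test_fit_line_matches_brute_force(points):
    xs = {round(p[0], 9) for p in points}
    ys = {round(p[1], 9) for p in points}
    if len(xs) < 2 or len(ys) < 2:
        return
    fit = dp.fit_line(points)
    slope, intercept, r2 = brute_force_ols(points)
    assert fit.slope == pytest.approx(slope, abs=1e-9, rel=1e-9)
    assert fit.intercept == pytest.approx(intercept, abs=1e-9, rel=1e-9)
    assert fit.r_squared == pytest.approx(r2, abs=1e-9)


def test_fit_line_errors():
    with pytest.raises(InsufficientDataError):
        dp.fit_line([(0, 1), (1, 2)])
    with pytest.raises(InsufficientDataError):
        dp.fit_line([(1, 1), (1, 2), (1, 3)])
    with pytest.raises(DegenerateFitError):
        dp.fit_line([(0, 5), (1, 5), (2, 5)])


@pytest.fixture
def blue_curve():
    return dp.CalibrationCurve(
        channel="blue", slope=-3.009, intercept=128.19, r_squared=0.992,
        linear_range=(2.5, 30.0),
    )


def test_back_calculate_inverts_line(blue_curve):
    conc, out = dp.back_calculate(blue_curve, 83.055)
    assert conc == pytest.approx(15.0)
    assert not out


def test_back_calculate_intercept_signal_is_out_of_range(blue_curve):
    conc, out = dp.back_calculate(blue_curve, 128.19)
    assert conc == pytest.approx(0.0)
    assert out


def test_back_calculate_zero_slope_errors():
    flat = dp.CalibrationCurve("blue", 0.0, 100.0, 0.5, (2.5, 30.0))
    with pytest.raises(DegenerateCurveError):
        dp.back_calculate(flat, 100.0)


def test_predict_then_backcalc_is_identity(blue_curve):
    for conc in (2.5, 7.7, 15.0, 29.9):
        back, out = dp.back_calculate(blue_curve, blue_curve.predict_signal(conc))
        assert back == pytest.approx(conc, abs=1e-9)
        assert not out


def test_linear_range_drops_clipped_low_standard(noiseless_model, read_standards):
    """The 1.0 % w/w standard sits on the clipped plateau and must be trimmed."""
    levels = (1.0, 2.52, 6.03, 10.07, 18.13, 23.32, 27.21, 30.03)
    obs, _ = read_standards(noiseless_model, levels)
    curve = dp.determine_linear_range(
        [(o.nominal_conc, o.signal("blue")) for o in obs]
    )
    assert curve.linear_range == (2.52, 30.03)
    assert len(curve.points) == 7


def test_linear_range_exact_line_keeps_everything():
    pts = [(c, 100 - 2 * c) for c in (1.0, 5.0, 10.0, 20.0, 30.0)]
    curve = dp.determine_linear_range(pts)
    assert curve.linear_range == (1.0, 30.0)
    assert curve.r_squared == pytest.approx(1.0)


def test_linear_range_flat_response_fails():
    with pytest.raises(NoLinearRangeError):
        dp.determine_linear_range([(1.0, 50.0), (5.0, 50.0), (10.0, 50.0), (20.0, 50.0)])


def test_linear_range_needs_enough_standards():
    with pytest.raises(InsufficientDataError):
        dp.determine_linear_range([(1, 10), (2, 20), (3, 30)])


def _clipped_signals(levels, clip_lo=2.52):
    return [(c, 128.19 - 3.009 * max(c, clip_lo)) for c in levels]


@pytest.mark.parametrize("r2_relax, bias_relax", [(0.0, 5.0), (0.01, 0.0), (0.01, 10.0)])
def test_linear_range_monotone_in_thresholds(r2_relax, bias_relax):
    """Relaxing either acceptance threshold never shrinks the retained range."""
    pts = _clipped_signals((1.0, 1.8, 2.52, 6.0, 12.0, 20.0, 30.0))
    strict = dp.determine_linear_range(pts, r2_min=0.98, backcalc_bias_max=15.0)
    relaxed = dp.determine_linear_range(
        pts, r2_min=0.98 - r2_relax, backcalc_bias_max=15.0 + bias_relax
    )
    assert relaxed.linear_range[0] <= strict.linear_range[0]
    assert relaxed.linear_range[1] >= strict.linear_range[1]


def _published_style_curves():
    return [
        dp.CalibrationCurve("red", -0.255, 187.04, 0.975, (8.1, 30.0)),
        dp.CalibrationCurve("green", -0.452, 171.90, 0.966, (8.1, 30.0)),
        dp.CalibrationCurve("blue", -3.009, 128.19, 0.992, (2.5, 30.0)),
        dp.CalibrationCurve("rgb_mean", -1.156, 160.31, 0.990, (2.5, 30.0)),
        dp.CalibrationCurve("saturation", 4.185, 79.49, 0.991, (2.5, 30.0)),
        dp.CalibrationCurve("brightness", -0.161, 185.96, 0.966, (2.5, 27.2)),
    ]


def test_select_channel_prefers_saturation_sensitivity():
    """Among the wide-range candidates passing R^2, saturation has the
    steepest slope and therefore the best sensitivity."""
    assert dp.select_channel(_published_style_curves(), r2_min=0.98) == "saturation"


def test_select_channel_single_candidate():
    curve = dp.CalibrationCurve("blue", -3.0, 128.0, 0.99, (2.5, 30.0))
    assert dp.select_channel([curve]) == "blue"


def test_select_channel_no_valid_candidate():
    weak = [dp.CalibrationCurve("blue", -3.0, 128.0, 0.90, (2.5, 30.0))]
    with pytest.raises(ChannelSelectionError):
        dp.select_channel(weak, r2_min=0.98)


def test_noiseless_pipeline_r2(noiseless_model, read_standards):
    obs, _ = read_standards(noiseless_model, (2.52, 6.03, 10.07, 18.13, 23.32, 30.03))
    fit = dp.fit_line([(o.nominal_conc, o.signal("blue")) for o in obs])
    assert fit.r_squared >= 0.999
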