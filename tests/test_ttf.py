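"""Time-to-foot detection, transit times, baseline correction, PWV."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pwvkit import (
    FlowCurve,
    InputError,
    NonPhysiologicTransitTime,
    NoUpstrokeError,
    ParameterError,
    SmoothingSpec,
    TtfConfig,
    WaveformParams,
    apply_baseline_correction,
    auto_baseline_offset,
    compute_pwv,
    detect_foot,
    generate_waveform,
    make_phantom_pair,
    measure_pwv,
    transit_time,
)

CYCLE = 1000.0
NO_SMOOTH = SmoothingSpec(sigma_ms=0.0)


def piecewise_linear_pulse(n=400, foot=100.0, slope=2.0, peak_t=250.0,
                           base=0.0):
    """Baseline then a linear rise: the tangent intersection is exact."""
    t = np.arange(n) * CYCLE / n
    f = np.full(n, base)
    rising = (t >= foot) & (t <= peak_t)
    f[rising] = base + slope * (t[rising] - foot)
    after = t > peak_t
    f[after] = base + slope * (peak_t - foot) * np.maximum(
        0.0, 1.0 - (t[after] - peak_t) / 200.0
    )
    return FlowCurve.uniform(f, CYCLE)


def chord_foot_oracle(params: WaveformParams, band=(0.2, 0.8)) -> float:
    """Independent dense least-squares oracle for the tangent-intersection
    foot of the analytic raised-cosine onset (horizontal baseline at the
    diastolic level)."""
    t = np.linspace(params.foot_time,
                    params.foot_time + params.upslope_duration, 200_001)
    f = params.evaluate(t)
    amp = params.peak_flow - params.diastolic_level
    lo = params.diastolic_level + band[0] * amp
    hi = params.diastolic_level + band[1] * amp
    sel = (f >= lo) & (f <= hi)
    slope, intercept = np.polyfit(t[sel], f[sel], 1)
    return (params.diastolic_level - intercept) / slope


class TestDetectFoot:
    def test_piecewise_linear_foot_is_exact(self):
        curve = piecewise_linear_pulse(n=400, foot=100.0)
        res = detect_foot(curve, smoothing=NO_SMOOTH)
        assert res.foot_time == pytest.approx(100.0, abs=0.5 * curve.dt)

    def test_piecewise_linear_foot_on_coarse_grid(self):
        curve = piecewise_linear_pulse(n=40, foot=100.0)
        res = detect_foot(curve, smoothing=NO_SMOOTH)
        assert res.foot_time == pytest.approx(100.0, abs=0.5 * curve.dt)

    def test_translation_equivariance(self):
        curve = piecewise_linear_pulse(n=400, foot=100.0)
        base = detect_foot(curve, smoothing=NO_SMOOTH).foot_time
        for shift_samples in (40, 160, 300):
            shifted = curve.with_flows(np.roll(curve.flows, shift_samples))
            s_ms = shift_samples * curve.dt
            got = detect_foot(shifted, smoothing=NO_SMOOTH).foot_time
            assert got == pytest.approx((base + s_ms) % CYCLE,
                                        abs=0.5 * curve.dt)

    def test_raised_cosine_foot_matches_dense_ls_oracle(
        self, default_params, dense_curve
    ):
        # the intersecting-tangent foot of a smooth onset sits after the
        # true onset; the oracle is an independent dense LS fit over the
        # same 20-80 % amplitude band
        expected = chord_foot_oracle(default_params)
        res = detect_foot(dense_curve)
        assert res.foot_time == pytest.approx(expected, abs=0.5)
        assert res.upslope.slope > 0
        assert res.upslope.r_squared > 0.98

    def test_upslope_window_inside_the_rise(self, dense_curve, default_params):
        res = detect_foot(dense_curve)
        lo, hi = res.upslope.fit_window
        assert default_params.foot_time <= lo < hi
        assert hi <= default_params.foot_time + default_params.upslope_duration

    def test_flat_curve_has_no_upstroke(self):
        curve = FlowCurve.uniform(np.zeros(100), CYCLE)
        with pytest.raises(NoUpstrokeError):
            detect_foot(curve, smoothing=NO_SMOOTH)

    def test_scale_equivariance_of_foot_time(self, default_params):
        curve = generate_waveform(default_params, 40)
        f1 = detect_foot(curve).foot_time
        f2 = detect_foot(curve.with_flows(curve.flows * 3.7)).foot_time
        assert f2 == pytest.approx(f1, abs=1e-6)


class TestTransitTime:
    def _foot(self, t):
        # transit_time only reads .foot_time; plain floats are accepted
        return t

    @pytest.mark.parametrize(
        "prox,dist,expected",
        [(80.0, 205.0, 125.0), (990.0, 15.0, 25.0), (10.0, 490.0, 480.0)],
    )
    def test_modular_difference(self, prox, dist, expected):
        assert transit_time(prox, dist, CYCLE) == pytest.approx(expected)

    @pytest.mark.parametrize("prox,dist", [(100.0, 100.0), (205.0, 80.0)])
    def test_zero_or_negative_raises_with_value(self, prox, dist):
        with pytest.raises(NonPhysiologicTransitTime) as exc:
            transit_time(prox, dist, CYCLE)
        assert exc.value.delta_t <= 0.0


class TestComputePwv:
    def test_simple_arithmetic(self):
        assert compute_pwv(250.0, 50.0) == pytest.approx(5.0)

    def test_healthy_young_example(self):
        # 250 mm plane distance and a 55.6 ms transit time give ~4.5 m/s,
        # a typical healthy-young aortic PWV
        assert compute_pwv(250.0, 55.6) == pytest.approx(4.496, abs=1e-3)

    def test_guards(self):
        with pytest.raises(NonPhysiologicTransitTime):
            compute_pwv(250.0, 0.0)
        with pytest.raises(ParameterError):
            compute_pwv(-1.0, 50.0)


class TestBaselineCorrection:
    def test_constant_curve_offset_is_the_constant(self):
        curve = FlowCurve.uniform(np.full(40, 13.5), CYCLE)
        assert auto_baseline_offset(curve) == pytest.approx(13.5)

    def test_default_waveform_offset_zero(self, default_params):
        curve = generate_waveform(default_params, 40)
        assert auto_baseline_offset(curve) == pytest.approx(0.0, abs=1e-9)

    def test_offset_linear_in_added_constant(self, default_params):
        curve = generate_waveform(default_params, 40)
        shifted = curve.with_flows(curve.flows + 17.0)
        assert auto_baseline_offset(shifted) == pytest.approx(17.0, abs=1e-9)

    def test_correction_idempotent(self, default_params):
        curve = generate_waveform(default_params, 40)
        shifted = curve.with_flows(curve.flows + 8.0)
        corrected = apply_baseline_correction(
            shifted, auto_baseline_offset(shifted)
        )
        assert auto_baseline_offset(corrected) == pytest.approx(0.0, abs=1e-9)

    def test_zero_offset_is_identity(self, default_params):
        curve = generate_waveform(default_params, 40)
        out = apply_baseline_correction(curve, 0.0)
        assert np.array_equal(out.flows, curve.flows)

    def test_regurgitation_breaks_the_automatic_window(self, default_params):
        # with genuine negative diastolic flow the automatic estimate picks
        # up the regurgitant mean -- the reason a manual path exists
        regurg = replace(default_params, diastolic_level=-25.0)
        curve = generate_waveform(regurg, 40)
        offset = auto_baseline_offset(curve)
        assert offset == pytest.approx(-25.0, abs=1e-6)
        assert abs(offset - 0.0) > 20.0  # far from the true (zero) offset


class TestMeasurePwv:
    @pytest.mark.parametrize("pwv_true", [2.0, 6.0, 12.0, 20.0])
    def test_dense_phantom_recovers_injected_pwv(self, default_params, pwv_true):
        prox, dist, _ = make_phantom_pair(default_params, pwv_true, 250.0,
                                          10_000)
        res = measure_pwv(prox, dist, 250.0)
        assert res.pwv == pytest.approx(pwv_true, rel=0.01)

    def test_zero_shift_pair_is_non_physiologic(self, default_params):
        prox = generate_waveform(default_params, 40)
        with pytest.raises(NonPhysiologicTransitTime):
            measure_pwv(prox, prox, 250.0)

    def test_recovery_within_plateau_band_at_35_frames(self, default_params):
        prox, dist, _ = make_phantom_pair(default_params, 8.0, 250.0, 35)
        res = measure_pwv(prox, dist, 250.0)
        assert abs(res.pwv - 8.0) / 8.0 <= 0.06

    def test_result_invariant_pwv_equals_distance_over_delta_t(
        self, default_params
    ):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        res = measure_pwv(prox, dist, 250.0)
        assert res.pwv == pytest.approx(res.distance / res.delta_t, rel=1e-12)
        assert res.delta_t > 0

    def test_scale_equivariance(self, default_params):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        res1 = measure_pwv(prox, dist, 250.0)
        res2 = measure_pwv(prox.with_flows(prox.flows * 5.0),
                           dist.with_flows(dist.flows * 5.0), 250.0)
        assert res2.pwv == pytest.approx(res1.pwv, rel=1e-9)
        assert res2.delta_t == pytest.approx(res1.delta_t, rel=1e-9)

    def test_common_time_shift_leaves_delta_t_unchanged(self, default_params):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        res1 = measure_pwv(prox, dist, 250.0)
        k = 7  # shift both curves by 7 frames (175 ms)
        res2 = measure_pwv(prox.with_flows(np.roll(prox.flows, k)),
                           dist.with_flows(np.roll(dist.flows, k)), 250.0)
        assert res2.delta_t == pytest.approx(res1.delta_t, abs=0.05)

    @settings(max_examples=15, derandomize=True)
    @given(factor=st.floats(0.25, 4.0))
    def test_pwv_homogeneous_in_distance(self, default_params, factor):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        base = measure_pwv(prox, dist, 250.0)
        scaled = measure_pwv(prox, dist, 250.0 * factor)
        assert scaled.pwv == pytest.approx(base.pwv * factor, rel=1e-12)

    def test_manual_baseline_mode_corrects_a_shifted_pair(self, default_params):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        prox_off = prox.with_flows(prox.flows + 30.0)
        dist_off = dist.with_flows(dist.flows + 30.0)
        cfg = replace(TtfConfig(), baseline_mode="manual", manual_offset=30.0)
        res = measure_pwv(prox_off, dist_off, 250.0, config=cfg)
        ref = measure_pwv(prox, dist, 250.0)
        assert res.pwv == pytest.approx(ref.pwv, rel=1e-6)

    def test_auto_baseline_mode_matches_uncorrected_clean_pair(
        self, default_params
    ):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        off = 12.0
        cfg = replace(TtfConfig(), baseline_mode="auto")
        res = measure_pwv(prox.with_flows(prox.flows + off),
                          dist.with_flows(dist.flows + off), 250.0, config=cfg)
        ref = measure_pwv(prox, dist, 250.0)
        assert res.pwv == pytest.approx(ref.pwv, rel=1e-3)

    def test_cycle_mismatch_rejected(self, default_params):
        prox, dist, _ = make_phantom_pair(default_params, 6.0, 250.0, 40)
        other = FlowCurve.uniform(dist.flows, 900.0)
        with pytest.raises(InputError):
            measure_pwv(prox, other, 250.0)
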