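"""Controller performance metrics and signal-agreement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resuscloop import (
    InfusionCommand,
    PressureTrace,
    ValidationError,
    agreement,
    area_metrics,
    degradation_suite,
    effectiveness,
    infusion_stats,
    mdpe_wobble,
    paired_agreement,
    performance_error_series,
    resuscitation_effectiveness,
    rise_time_efficiency,
)


def make_trace(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return PressureTrace(np.arange(values.size) * dt, values)


class TestPerformanceError:
    def test_at_target_zero(self, constant_trace):
        pe = performance_error_series(constant_trace(65.0), 65.0)
        assert np.all(pe == 0.0)

    @pytest.mark.parametrize("map_val, target, expected", [
        (71.5, 65.0, 10.0),
        (58.5, 65.0, -10.0),
    ])
    def test_percent_deviation(self, constant_trace, map_val, target, expected):
        pe = performance_error_series(constant_trace(map_val), target)
        assert pe[0] == pytest.approx(expected)


class TestBandMetrics:
    def test_always_in_band_is_100(self, constant_trace):
        assert effectiveness(constant_trace(65.0), 65.0) == 100.0

    def test_half_in_band_is_50(self):
        trace = make_trace([65.0] * 50 + [55.0] * 50)
        assert effectiveness(trace, 65.0) == 50.0

    def test_overshoot_penalized_only_by_effectiveness(self, constant_trace):
        trace = constant_trace(85.0)
        assert effectiveness(trace, 65.0) == 0.0
        assert resuscitation_effectiveness(trace, 65.0) == 100.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_band_metrics_match_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(30.0, 90.0, size=rng.integers(2, 200))
        trace = make_trace(vals)
        target, band = 65.0, 5.0
        n_eff = sum(1 for v in vals if abs(v - target) <= band)
        n_res = sum(1 for v in vals if v >= target - band)
        assert effectiveness(trace, target) == pytest.approx(100 * n_eff / vals.size)
        assert resuscitation_effectiveness(trace, target) == pytest.approx(
            100 * n_res / vals.size
        )
        assert resuscitation_effectiveness(trace, target) >= effectiveness(
            trace, target
        )


class TestRiseTime:
    def test_starting_in_band_is_zero(self, constant_trace):
        assert rise_time_efficiency(constant_trace(64.0), 65.0) == 0.0

    def test_linear_rise_hand_computed(self):
        t = np.arange(0.0, 601.0)
        trace = PressureTrace(t, 30.0 + 6.0 * t / 60.0)  # 6 mmHg/min
        assert rise_time_efficiency(trace, 65.0, band=5.0) == pytest.approx(5.0)

    def test_never_reached_flagged_as_nan(self, constant_trace):
        assert np.isnan(rise_time_efficiency(constant_trace(40.0), 65.0))


class TestMdpeWobble:
    def test_constant_offset(self):
        mdpe, wobble = mdpe_wobble(np.full(10, 10.0))
        assert (mdpe, wobble) == (10.0, 0.0)

    def test_hand_medians(self):
        mdpe, wobble = mdpe_wobble(np.array([-1.0, 0.0, 1.0]))
        assert (mdpe, wobble) == (0.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(-50.0, 50.0))
    def test_wobble_shift_invariant(self, seed, shift):
        pe = np.random.default_rng(seed).normal(0, 5, size=31)
        _, w0 = mdpe_wobble(pe)
        _, w1 = mdpe_wobble(pe + shift)
        assert w1 == pytest.approx(w0, abs=1e-9)


class TestAreas:
    def test_constant_offset_area(self):
        t = np.arange(0.0, 3600.0)  # 60 min at 1 Hz
        trace = PressureTrace(t, np.full(t.size, 75.0))
        above, below = area_metrics(trace, 65.0)
        assert above == pytest.approx(600.0)
        assert below == 0.0

    def test_at_target_zero_both(self, constant_trace):
        above, below = area_metrics(constant_trace(65.0), 65.0)
        assert (above, below) == (0.0, 0.0)

    def test_symmetric_sawtooth_balances(self):
        cycle = np.concatenate([np.linspace(-10, 10, 50), np.linspace(10, -10, 50)])
        trace = make_trace(65.0 + np.tile(cycle, 10))
        above, below = area_metrics(trace, 65.0)
        assert above == pytest.approx(below, rel=0.01)

    def test_matches_trapezoid_oracle_on_smooth_trace(self):
        t = np.arange(0.0, 1800.0)
        v = 65.0 + 8.0 * np.sin(2 * np.pi * t / 600.0)
        trace = PressureTrace(t, v)
        above, _ = area_metrics(trace, 65.0)
        oracle = np.trapezoid(np.maximum(v - 65.0, 0.0), t / 60.0)
        assert above == pytest.approx(oracle, rel=0.01)


class TestInfusionStats:
    def test_constant_rate(self):
        cmds = [InfusionCommand(0.0, 30.0), InfusionCommand(100.0, 30.0)]
        mean, median, sd = infusion_stats(cmds, (0.0, 200.0))
        assert (mean, median, sd) == (30.0, 30.0, 0.0)

    def test_two_level_split(self):
        cmds = [InfusionCommand(0.0, 0.0), InfusionCommand(100.0, 60.0)]
        mean, median, sd = infusion_stats(cmds, (0.0, 200.0))
        assert mean == pytest.approx(30.0)
        assert median == pytest.approx(30.0)
        assert sd == pytest.approx(30.0)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            infusion_stats([], (0.0, 100.0))


class TestAgreement:
    def test_identical_traces(self, affine_trace):
        rep = agreement(affine_trace(), affine_trace())
        assert rep.r2 == pytest.approx(1.0)
        assert rep.rmse == 0.0
        assert rep.accuracy == 100.0
        assert rep.bias == 0.0

    def test_constant_offset_boundary_inclusive(self, affine_trace):
        ref = affine_trace()
        test = PressureTrace(ref.times, ref.values + 10.0)
        rep = agreement(test, ref)
        assert rep.rmse == pytest.approx(10.0)
        assert rep.accuracy == 100.0  # |diff| == 10 counts as within range

    def test_zero_readings_reduce_reliability(self):
        test = np.array([60.0, 0.0, 62.0, 0.0, 64.0, 65.0, 66.0, 67.0])
        ref = np.full(8, 64.0)
        rep = paired_agreement(test, ref)
        assert rep.reliability == pytest.approx(75.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            paired_agreement(np.array([65.0]), np.array([64.0]))

    def test_bland_altman_limits_cover_95_percent(self):
        rng = np.random.default_rng(7)
        n = 10_000
        ref = rng.uniform(40.0, 80.0, n)
        test = ref + rng.normal(1.0, 3.0, n)
        rep = paired_agreement(test, ref)
        diff = test - ref
        inside = np.mean((diff >= rep.loa_low) & (diff <= rep.loa_high))
        assert inside == pytest.approx(0.95, abs=0.02)


class TestDegradationSuite:
    def test_upsampled_exact_on_affine_signal(self, affine_trace):
        reps = degradation_suite(affine_trace(duration=600.0), seed=0)
        assert reps["upsampled"].r2 == pytest.approx(1.0, abs=1e-6)

    def test_upsampled_noisier_than_hold_on_turning_signal(self):
        # slope reversals between 60-s samples make extrapolation overshoot
        t = np.arange(0.0, 901.0)
        trace = PressureTrace(t, 65.0 + 8.0 * np.sin(2 * np.pi * t / 150.0))
        reps = degradation_suite(trace, seed=0)
        assert reps["upsampled"].rmse >= reps["intermittent"].rmse

    def test_hold_identity_on_constant_signal(self, constant_trace):
        reps = degradation_suite(constant_trace(duration=600.0), seed=0)
        assert reps["intermittent"].rmse == 0.0
        assert reps["intermittent"].accuracy == 100.0
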