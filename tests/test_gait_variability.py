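"""Variability-feature tests: windowing, summaries, reductions, decay fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitadapt.gait_variability import (
    build_feature_windows,
    fit_indicator_decay,
    percent_reduction,
    steady_state_summary,
    windowed_variance,
)
from gaitadapt.types import GaitCycle, VariabilityWindow


def _cycles(sf, mhf, mhe, block=0, day=1, t0=0.0):
    out = []
    t = t0
    for f, a, b in zip(sf, mhf, mhe):
        out.append(
            GaitCycle(
                start_time=t,
                stride_time=1.0 / f,
                mhf_angle=a,
                mhe_angle=b,
                exposure_time=t / 60.0,
                subject_id="S1",
                day_index=day,
                block_index=block,
            )
        )
        t += 1.0 / f
    return out


def _window(var_sf, exposure, idx=0, day=1):
    return VariabilityWindow(
        var_sf=var_sf,
        var_mhf=var_sf,
        var_mhe=var_sf,
        exposure_time=exposure,
        window_index=idx,
        subject_id="S1",
        day_index=day,
    )


class TestWindowedVariance:
    def test_identical_values_have_zero_variance(self):
        np.testing.assert_array_equal(windowed_variance(np.full(10, 3.3)), [0.0])

    def test_matches_brute_force_sample_variance(self):
        vals = np.arange(1.0, 11.0)
        expected = sum((v - vals.mean()) ** 2 for v in vals) / 9  # 9.1667
        assert windowed_variance(vals)[0] == pytest.approx(expected)
        assert expected == pytest.approx(9.1667, abs=1e-4)

    def test_trailing_remainder_dropped(self):
        out = windowed_variance(np.arange(25.0), window=10)
        assert out.shape == (2,)

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            windowed_variance(np.arange(10.0), window=1)

    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance_and_scale_covariance(self, shift, scale):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=30)
        base = windowed_variance(vals)
        np.testing.assert_allclose(windowed_variance(vals + shift), base, atol=1e-9)
        np.testing.assert_allclose(
            windowed_variance(vals * scale), base * scale**2, rtol=1e-9
        )


class TestBuildFeatureWindows:
    def test_noiseless_cycles_give_zero_variances(self):
        cycles = _cycles([0.9] * 30, [30.0] * 30, [-17.0] * 30)
        windows = build_feature_windows(cycles)
        assert len(windows) == 3
        for w in windows:
            assert w.var_sf == pytest.approx(0.0, abs=1e-24)
            assert w.var_mhf == pytest.approx(0.0, abs=1e-24)
            assert w.var_mhe == pytest.approx(0.0, abs=1e-24)

    def test_windows_never_span_blocks(self):
        cycles = _cycles([0.9] * 15, [30.0] * 15, [-17.0] * 15, block=0)
        cycles += _cycles([0.9] * 15, [30.0] * 15, [-17.0] * 15, block=1)
        windows = build_feature_windows(cycles)
        # 15 cycles per block -> 1 window each, 5 dropped per block
        assert len(windows) == 2

    def test_window_partition_tiles_cycles(self):
        cycles = _cycles([0.9] * 43, [30.0] * 43, [-17.0] * 43)
        windows = build_feature_windows(cycles, window=10)
        assert len(windows) == 4
        assert [w.window_index for w in windows] == [0, 1, 2, 3]

    def test_stationary_variance_estimates_unbiased(self, rng):
        # windows of n=10 -> chi-square spread, but the mean is unbiased
        true_var = 0.01
        vals = rng.normal(0.0, np.sqrt(true_var), size=3000)
        est = windowed_variance(vals, window=10)
        assert np.mean(est) == pytest.approx(true_var, rel=0.15)

    def test_exposure_stamp_is_mean_cycle_exposure(self):
        cycles = _cycles([1.0] * 10, [30.0] * 10, [-17.0] * 10)
        w = build_feature_windows(cycles)[0]
        assert w.exposure_time == pytest.approx(
            np.mean([c.exposure_time for c in cycles])
        )


class TestSteadyStateSummary:
    def test_constant_windows(self):
        windows = [_window(0.5, 37.0 + 0.2 * i, i) for i in range(15)]
        out = steady_state_summary(windows, minutes=3.0)
        assert out["sf"] == pytest.approx(0.5)

    def test_decaying_variance_summary_below_session_mean(self):
        windows = [_window(1.0 * np.exp(-i / 20), i, i) for i in range(40)]
        out = steady_state_summary(windows, minutes=3.0)
        assert out["sf"] < np.mean([w.var_sf for w in windows])

    def test_empty_input_is_missing(self):
        assert steady_state_summary([]) is None


class TestPercentReduction:
    @pytest.mark.parametrize(
        "day1,day6,expected",
        [(1.0, 1.0, 0.0), (1.0, 0.336, 66.4), (0.5, 1.0, -100.0)],
    )
    def test_values(self, day1, day6, expected):
        assert percent_reduction(day1, day6) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_reduction(0.0, 1.0)


class TestFitIndicatorDecay:
    def test_noiseless_windows_recover_tau(self):
        v0, vss, tau = 4e-4, 4e-5, 180.0
        t = np.linspace(0, 240, 120)
        windows = [
            _window(vss + (v0 - vss) * np.exp(-x / tau), x, i)
            for i, x in enumerate(t)
        ]
        fit = fit_indicator_decay(windows, "sf")
        assert fit.converged
        assert fit.tau == pytest.approx(tau, rel=0.02)

    def test_constant_series_flagged(self):
        windows = [_window(0.5, float(i), i) for i in range(20)]
        fit = fit_indicator_decay(windows, "sf")
        assert not fit.converged

    def test_monte_carlo_recovery_under_sampling_noise(self, rng):
        # windows are n=10 sample variances (chi-square noise around v(t));
        # the window count matches a full six-day protocol (~1300 windows)
        v0, vss, tau = 4e-4, 4e-5, 150.0
        t = np.linspace(0, 240, 1300)
        errors = []
        for _ in range(20):
            v_true = vss + (v0 - vss) * np.exp(-t / tau)
            draws = rng.normal(size=(t.size, 10)) * np.sqrt(v_true)[:, None]
            windows = [
                _window(float(np.var(d, ddof=1)), x, i)
                for i, (x, d) in enumerate(zip(t, draws))
            ]
            fit = fit_indicator_decay(windows, "sf")
            errors.append(abs(fit.tau - tau) / tau)
        assert np.median(errors) < 0.15

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            fit_indicator_decay([_window(1.0, 0.0)], "stride")
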