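"""Kinematics tests: calibration, filtering, event detection, segmentation."""

import numpy as np
import pytest

from gaitadapt.imu_kinematics import (
    calibrate_standing,
    detect_events,
    lowpass,
    process_block,
    segment_cycles,
)
from gaitadapt.synthetic_cohort import simulate_thigh_angle
from gaitadapt.types import GaitEvent, ThighAngleSeries


def _series(angle, rate=400.0, **kw):
    return ThighAngleSeries(angle=np.asarray(angle, dtype=float), rate=rate, **kw)


def _sinusoid(amplitude=30.0, offset=10.0, period=1.1, duration=22.0, rate=400.0):
    t = np.arange(int(duration * rate)) / rate
    return _series(offset + amplitude * np.sin(2 * np.pi * t / period), rate)


class TestCalibrateStanding:
    def test_subtracts_standing_mean(self):
        standing = _series(np.full(2000, 2.3))
        series = _series(np.full(4000, 32.3))
        out = calibrate_standing(series, standing)
        np.testing.assert_allclose(out.angle, 30.0)

    def test_series_against_itself_is_zero(self):
        s = _sinusoid()
        out = calibrate_standing(s, _series(np.full(2000, float(s.angle.mean()))))
        assert abs(out.angle.mean()) < 1e-9

    def test_offset_propagates_to_detected_peaks(self, noiseless_profile, day1_schedule, noiseless_config):
        block = simulate_thigh_angle(
            noiseless_profile, day1_schedule, 0.0, 4, noiseless_config,
            calibration_offset=5.0,
        )[0]
        standing = _series(np.full(2000, 5.0))
        raw = process_block(block, cutoff=7.0)
        cal = process_block(block, standing=standing, cutoff=7.0)
        shift = np.mean([a.mhf_angle for a in raw]) - np.mean([c.mhf_angle for c in cal])
        assert shift == pytest.approx(5.0, abs=1e-6)

    def test_short_standing_trial_rejected(self):
        with pytest.raises(ValueError):
            calibrate_standing(_sinusoid(), _series(np.zeros(100)))


class TestLowpass:
    def test_passband_sinusoid_preserved(self):
        s = _sinusoid(amplitude=30.0, offset=0.0, period=1.0)  # 1 Hz
        out = lowpass(s, 7.0)
        spec_in = np.abs(np.fft.rfft(s.angle))
        spec_out = np.abs(np.fft.rfft(out.angle))
        k = spec_in.argmax()
        assert spec_out[k] / spec_in[k] == pytest.approx(1.0, abs=0.01)
        # zero phase: cross-correlation peak at zero lag
        lag = np.argmax(np.correlate(out.angle, s.angle, "full")) - (s.angle.size - 1)
        assert lag == 0

    def test_stopband_sinusoid_attenuated(self):
        s = _sinusoid(amplitude=10.0, offset=0.0, period=0.02)  # 50 Hz
        out = lowpass(s, 7.0)
        interior = out.angle[400:-400]  # skip forward-backward edge transients
        assert np.abs(interior).max() < 0.1 * 10.0

    def test_dc_preserved(self):
        out = lowpass(_series(np.full(4000, 4.2)), 7.0)
        np.testing.assert_allclose(out.angle, 4.2, rtol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass(_sinusoid(), 200.0)


class TestDetectEvents:
    def test_sinusoid_peak_locations_and_angles(self):
        s = _sinusoid(amplitude=30.0, offset=10.0, period=1.1, duration=22.0)
        events = detect_events(s)
        mhf = [e for e in events if e.kind == "mhf"]
        mhe = [e for e in events if e.kind == "mhe"]
        assert len(mhf) == 20
        np.testing.assert_allclose(np.diff([e.time for e in mhf]), 1.1, atol=1 / 400)
        np.testing.assert_allclose([e.angle for e in mhf], 40.0, atol=0.01)
        np.testing.assert_allclose([e.angle for e in mhe], -20.0, atol=0.01)

    def test_constant_signal_yields_no_events(self):
        assert detect_events(_series(np.full(8000, 3.0))) == []

    def test_events_strictly_alternate(self, profile, day1_schedule, base_config):
        block = simulate_thigh_angle(profile, day1_schedule, 0.0, 8, base_config)[0]
        events = detect_events(lowpass(block, 7.0))
        kinds = [e.kind for e in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestSegmentCycles:
    def test_arithmetic_from_event_times(self):
        events = [
            GaitEvent(0.0, 40.0, "mhf"),
            GaitEvent(0.68, -20.0, "mhe"),
            GaitEvent(1.1, 40.0, "mhf"),
            GaitEvent(1.78, -20.0, "mhe"),
            GaitEvent(2.2, 40.0, "mhf"),
        ]
        cycles = segment_cycles(events)
        assert len(cycles) == 2
        assert cycles[0].stride_time == pytest.approx(1.1)
        assert cycles[0].step_frequency == pytest.approx(0.9091, abs=1e-4)
        assert cycles[0].mhe_angle == pytest.approx(-20.0)

    def test_single_mhf_yields_no_cycles(self):
        events = [GaitEvent(0.0, 40.0, "mhf"), GaitEvent(0.68, -20.0, "mhe")]
        assert segment_cycles(events) == []

    def test_missing_trough_drops_cycle(self):
        events = [
            GaitEvent(0.0, 40.0, "mhf"),
            GaitEvent(1.1, 40.0, "mhf"),
            GaitEvent(1.78, -20.0, "mhe"),
            GaitEvent(2.2, 40.0, "mhf"),
        ]
        cycles = segment_cycles(events)
        assert len(cycles) == 1
        assert cycles[0].start_time == pytest.approx(1.1)

    def test_exposure_stamps_accumulate_within_block(self):
        events = []
        for k in range(12):
            events.append(GaitEvent(1.1 * k, 40.0, "mhf"))
            events.append(GaitEvent(1.1 * k + 0.68, -20.0, "mhe"))
        cycles = segment_cycles(events, exposure_start=10.0)
        assert cycles[0].exposure_time == pytest.approx(10.0)
        assert cycles[-1].exposure_time == pytest.approx(10.0 + 1.1 * 10 / 60.0)


class TestPipelineRecovery:
    def test_noiseless_block_recovers_generator_parameters(
        self, noiseless_profile, day1_schedule, noiseless_config
    ):
        block = simulate_thigh_angle(
            noiseless_profile, day1_schedule, 0.0, 4, noiseless_config
        )[0]
        cycles = process_block(block, cutoff=7.0)
        assert len(cycles) > 250
        st = np.array([c.stride_time for c in cycles])
        mhf = np.array([c.mhf_angle for c in cycles])
        mhe = np.array([c.mhe_angle for c in cycles])
        assert np.abs(st - 1.1).max() <= 1 / 400 + 1e-12
        assert np.abs(mhf - noiseless_profile.mhf_mean).max() <= 0.1
        assert np.abs(mhe - noiseless_profile.mhe_mean).max() <= 0.1

    def test_stride_times_robust_to_white_noise(
        self, noiseless_profile, day1_schedule, noiseless_config, rng
    ):
        block = simulate_thigh_angle(
            noiseless_profile, day1_schedule, 0.0, 4, noiseless_config
        )[0]
        clean = process_block(block, cutoff=7.0)
        noisy_series = block.replace_angle(block.angle + rng.normal(0, 0.5, block.angle.size))
        noisy = process_block(noisy_series, cutoff=7.0)
        n = min(len(clean), len(noisy))
        dt = np.abs(
            np.array([c.stride_time for c in clean[:n]])
            - np.array([c.stride_time for c in noisy[:n]])
        )
        assert np.mean(dt <= 1 / 400 + 1e-12) >= 0.99
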