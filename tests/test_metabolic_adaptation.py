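"""Metabolic-cost tests: Brockway, normalization, curve fit, adaptation."""

import dataclasses

import numpy as np
import pytest

from gaitadapt.metabolic_adaptation import (
    adaptation_level,
    block_cost,
    brockway_power,
    fit_adaptation_curve,
    ground_truth_labels,
    normalize_daily,
    session_costs,
    time_to_adaptation,
)
from gaitadapt.synthetic_cohort import (
    brockway_gas_for_power,
    default_schedule,
    simulate_breath_series,
)
from gaitadapt.types import AdaptationCurve, BreathSeries, VariabilityWindow


def _breath_from_power(power, dt=3.0, kind="withsuit"):
    power = np.asarray(power, dtype=float)
    vo2, vco2 = brockway_gas_for_power(power)
    n = power.size
    return BreathSeries(
        time=np.arange(1, n + 1) * dt,
        vo2=vo2,
        vco2=vco2,
        block_index=np.zeros(n, dtype=int),
        block_kind=np.array([kind] * n, dtype=object),
    )


class TestBrockwayPower:
    def test_zero_input(self):
        assert brockway_power(0.0, 0.0) == 0.0

    def test_reference_arithmetic(self):
        # 16.58 * 4 ml/s + 4.51 * 3.2 ml/s
        assert brockway_power(240.0, 192.0) == pytest.approx(80.752)

    def test_linearity(self):
        assert brockway_power(480.0, 384.0) == pytest.approx(2 * brockway_power(240.0, 192.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            brockway_power(-1.0, 0.0)


class TestBlockCost:
    def test_resting_power_gives_zero_net_cost(self):
        series = _breath_from_power(np.full(80, 120.0))
        assert block_cost(series, 0, 120.0, 70.0, tail_minutes=2.0) == pytest.approx(0.0)

    def test_known_target_net_power(self):
        series = _breath_from_power(np.full(80, 250.0 + 90.0))
        cost = block_cost(series, 0, 90.0, 73.42, tail_minutes=2.0)
        assert cost == pytest.approx(250.0 / 73.42, abs=1e-9)
        assert cost == pytest.approx(3.405, abs=1e-3)

    def test_noisy_block_within_three_standard_errors(self, rng):
        target, resting, mass = 340.0, 90.0, 73.42
        n = 2000
        power = target * rng.normal(1.0, 0.05, size=n)
        series = _breath_from_power(power, dt=1.0)
        cost = block_cost(series, 0, resting, mass, tail_minutes=n / 60.0)
        se = 0.05 * target / np.sqrt(n) / mass
        assert abs(cost - (target - resting) / mass) < 3 * se

    def test_short_block_is_missing(self):
        series = _breath_from_power(np.full(10, 200.0))
        assert block_cost(series, 0, 90.0, 70.0, tail_minutes=2.0) is None


class TestNormalizeDaily:
    def test_equal_costs_are_100_percent(self):
        assert normalize_daily(3.0, 3.0) == pytest.approx(100.0)

    def test_nine_percent_reduction_scale(self):
        assert normalize_daily(0.91 * 3.3, 3.3) == pytest.approx(91.0)

    def test_day_drift_cancels(self):
        ws, ns, drift = 3.1, 3.4, 1.07
        assert normalize_daily(ws * drift, ns * drift) == pytest.approx(
            normalize_daily(ws, ns)
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_daily(3.0, 0.0)


class TestFitAdaptationCurve:
    def test_noiseless_points_recovered_exactly(self):
        t = np.linspace(0, 240, 48)
        y = 91.0 + (100.0 - 91.0) * np.exp(-t / 202.0)
        curve = fit_adaptation_curve(list(zip(t, y)))
        assert curve.converged
        assert curve.tau == pytest.approx(202.0, rel=1e-6)
        assert curve.cost0 == pytest.approx(100.0, rel=1e-6)
        assert curve.cost_ss == pytest.approx(91.0, rel=1e-6)

    def test_constant_series_flagged(self):
        curve = fit_adaptation_curve([(float(i), 95.0) for i in range(10)])
        assert not curve.converged

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_adaptation_curve([(0.0, 100.0)] * 3)

    def test_monte_carlo_recovery_from_breath_noise(
        self, noiseless_profile, noiseless_config
    ):
        """tau recovery from 6 simulated days at 5% breath-level noise."""
        # the profile keeps its sampled cost decay amplitude; only the time
        # constant and the breath noise are pinned
        profile = dataclasses.replace(noiseless_profile, tau=150.0, breath_cv=0.05)
        errors = []
        for rep in range(20):
            pts = []
            exposure = 0.0
            for d in range(1, 7):
                sched = default_schedule(d)
                series = simulate_breath_series(
                    profile, sched, exposure, 1000 * rep + d, config=noiseless_config
                )
                pts.extend(
                    session_costs(
                        series, sched, profile.resting_power, profile.body_mass, exposure
                    )
                )
                exposure += sched.withsuit_seconds / 60.0
            assert len(pts) == 48  # 8 blocks x 6 days
            curve = fit_adaptation_curve(pts)
            errors.append(abs(curve.tau - 150.0) / 150.0)
        assert np.median(errors) < 0.20


class TestAdaptationLevel:
    CURVE = AdaptationCurve(cost0=100.0, cost_ss=91.0, tau=202.0)

    def test_zero_at_first_exposure(self):
        assert adaptation_level(self.CURVE, 0.0) == 0.0

    def test_one_time_constant(self):
        assert adaptation_level(self.CURVE, 202.0) == pytest.approx(63.212, abs=1e-3)

    def test_strictly_increasing_and_bounded(self):
        t = np.linspace(0, 2000, 500)
        a = adaptation_level(self.CURVE, t)
        assert np.all(np.diff(a) > 0)
        assert a[0] == 0.0 and a[-1] < 100.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            adaptation_level(self.CURVE, -1.0)


class TestTimeToAdaptation:
    CURVE = AdaptationCurve(cost0=100.0, cost_ss=91.0, tau=202.0)

    def test_closed_form(self):
        expected = 202.0 * np.log(9.0 / (0.05 * 91.0))
        assert time_to_adaptation(self.CURVE) == pytest.approx(expected)
        assert expected == pytest.approx(137.8, abs=0.1)

    def test_already_within_band(self):
        curve = AdaptationCurve(cost0=92.0, cost_ss=91.0, tau=202.0)
        assert time_to_adaptation(curve) == 0.0

    def test_linear_in_tau(self):
        doubled = AdaptationCurve(cost0=100.0, cost_ss=91.0, tau=404.0)
        assert time_to_adaptation(doubled) == pytest.approx(
            2 * time_to_adaptation(self.CURVE)
        )

    def test_amplitude_mode(self):
        assert time_to_adaptation(self.CURVE, mode="amplitude") == pytest.approx(
            202.0 * np.log(20.0)
        )


class TestGroundTruthLabels:
    CURVE = AdaptationCurve(cost0=100.0, cost_ss=91.0, tau=100.0)

    def _windows(self, exposures):
        return [
            VariabilityWindow(0.1, 0.1, 0.1, e, i, "S1", 1)
            for i, e in enumerate(exposures)
        ]

    def test_zero_exposure_zero_label(self):
        labels = ground_truth_labels(self.CURVE, self._windows([0.0]))
        assert labels[0] == 0.0

    def test_labels_nondecreasing(self):
        labels = ground_truth_labels(self.CURVE, self._windows(np.linspace(0, 240, 50)))
        assert np.all(np.diff(labels) >= 0)

    def test_three_time_constants(self):
        labels = ground_truth_labels(self.CURVE, self._windows([300.0]))
        assert labels[0] == pytest.approx(95.02, abs=0.01)
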