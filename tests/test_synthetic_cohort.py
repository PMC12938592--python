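"""Generator tests: profile sampling, schedules, decay laws, round trips."""

import dataclasses

import numpy as np
import pytest

from gaitadapt.synthetic_cohort import (
    GeneratorConfig,
    brockway_gas_for_power,
    cost_percent_at,
    default_schedule,
    generate_cohort,
    generate_profile,
    simulate_breath_series,
    simulate_thigh_angle,
    variance_at,
)
from gaitadapt.metabolic_adaptation import brockway_power


class TestGenerateProfile:
    def test_degenerate_config_pins_tau_to_population_mean(self, base_config):
        cfg = dataclasses.replace(base_config, tau_sd=0.0, tau_var_log_sd=0.0)
        prof = generate_profile(cfg, rng_seed=7)
        assert prof.tau == pytest.approx(202.0)
        assert prof.tau_var == pytest.approx(202.0)

    def test_same_seed_gives_identical_profiles(self, base_config):
        assert generate_profile(base_config, 99) == generate_profile(base_config, 99)

    def test_tau_sampling_distribution(self, base_config):
        # bounds truncate mildly, so allow 3 SE around the nominal mean
        taus = [generate_profile(base_config, s).tau for s in range(1000)]
        se = base_config.tau_sd / np.sqrt(len(taus))
        assert abs(np.mean(taus) - base_config.tau_mean) < 4 * se

    def test_invariants_hold_across_many_draws(self, base_config):
        for seed in range(50):
            p = generate_profile(base_config, seed)
            assert p.tau > 0 and p.cost0 >= p.cost_ss > 0
            assert p.var0_sf >= p.varss_sf >= 0
            assert p.mhf_mean > p.mhe_mean

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(tau_mean=-5.0)


class TestDefaultSchedule:
    def test_withsuit_exposure_totals_40_minutes(self, day1_schedule):
        assert day1_schedule.withsuit_seconds == pytest.approx(2400.0)

    def test_eight_test_cycles(self, day1_schedule):
        assert len(day1_schedule.blocks_of("withsuit")) == 8
        assert len(day1_schedule.blocks_of("nosuit")) == 8

    @pytest.mark.parametrize("day", [1, 3, 6])
    def test_starts_with_standing(self, day):
        assert default_schedule(day).blocks[0].kind == "standing"

    @pytest.mark.parametrize("day", [0, 7, -1])
    def test_day_out_of_range(self, day):
        with pytest.raises(ValueError):
            default_schedule(day)


class TestDecayLaws:
    def test_variance_closed_form_at_one_time_constant(self):
        varss = 0.01
        var0 = 9 * varss
        assert variance_at(var0, varss, 150.0, 150.0) == pytest.approx(
            varss * (1 + 8 * np.exp(-1.0))
        )

    def test_variance_schedule_monotone_nonincreasing(self, profile):
        t = np.linspace(0, 240, 100)
        v = [variance_at(profile.var0_sf, profile.varss_sf, profile.tau_var, x) for x in t]
        assert np.all(np.diff(v) <= 1e-15)

    def test_cost_closed_form_at_one_time_constant(self, noiseless_profile):
        p = noiseless_profile
        expected = p.cost_ss + (p.cost0 - p.cost_ss) * np.exp(-1.0)
        assert cost_percent_at(p, p.tau) == pytest.approx(expected)


class TestThighAngleSimulation:
    def test_same_seed_bit_identical(self, profile, day1_schedule, base_config):
        a = simulate_thigh_angle(profile, day1_schedule, 0.0, 5, base_config)
        b = simulate_thigh_angle(profile, day1_schedule, 0.0, 5, base_config)
        assert len(a) == len(b) == 8
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.angle, y.angle)

    def test_blocks_carry_exposure_offsets(self, profile, day1_schedule, base_config):
        blocks = simulate_thigh_angle(profile, day1_schedule, 12.0, 5, base_config)
        starts = [b.exposure_start for b in blocks]
        assert starts == pytest.approx([12.0 + 5.0 * k for k in range(8)])

    def test_sample_rate_and_duration(self, profile, day1_schedule, base_config):
        block = simulate_thigh_angle(profile, day1_schedule, 0.0, 5, base_config)[0]
        assert block.rate == 400.0
        assert block.duration == pytest.approx(300.0, abs=3.0)


class TestBreathSimulation:
    def test_noiseless_standing_reproduces_resting_power(
        self, noiseless_profile, day1_schedule, noiseless_config
    ):
        bs = simulate_breath_series(
            noiseless_profile, day1_schedule, 0.0, 3, config=noiseless_config
        )
        standing = bs.block_kind == "standing"
        p = brockway_power(bs.vo2[standing], bs.vco2[standing])
        np.testing.assert_allclose(p, noiseless_profile.resting_power, rtol=1e-9)

    def test_noiseless_withsuit_cost_matches_decay_law(
        self, noiseless_profile, noiseless_config
    ):
        # start a session exactly at one time constant of prior exposure
        p = noiseless_profile
        sched = default_schedule(1)
        bs = simulate_breath_series(p, sched, p.tau, 3, config=noiseless_config)
        first_ws = sched.blocks_of("withsuit")[0][0]
        sel = bs.block_index == first_ws
        gross = brockway_power(bs.vo2[sel][0], bs.vco2[sel][0])
        net = gross - p.resting_power
        cost_pct = 100.0 * net / p.baseline_net_power
        expected = p.cost_ss + (p.cost0 - p.cost_ss) * np.exp(-1.0)
        assert cost_pct == pytest.approx(expected, rel=1e-3)

    def test_breath_noise_cv_calibrated(self, profile, base_config):
        # many breaths at a fixed target: empirical CV within 10% of nominal
        prof = dataclasses.replace(profile, breath_cv=0.05)
        sched = default_schedule(1)
        rng = np.random.default_rng(11)
        powers = []
        for seed in range(8):
            bs = simulate_breath_series(prof, sched, 1e6, seed, config=base_config)
            # far beyond tau the with-suit target is constant (= plateau)
            sel = bs.block_kind == "withsuit"
            powers.append(brockway_power(bs.vo2[sel], bs.vco2[sel]))
        p = np.concatenate(powers)
        assert p.size > 4000
        cv = p.std() / p.mean()
        assert abs(cv - 0.05) < 0.005

    def test_brockway_inversion_round_trip(self):
        target = np.array([80.0, 250.0, 430.0])
        vo2, vco2 = brockway_gas_for_power(target)
        np.testing.assert_allclose(brockway_power(vo2, vco2), target, rtol=1e-12)


class TestGenerateCohort:
    def test_structure_and_determinism(self):
        cfg = GeneratorConfig(n_days=2, schedule_scale=0.1)
        a = generate_cohort(2, cfg, master_seed=3)
        b = generate_cohort(2, cfg, master_seed=3)
        assert a.subject_ids == ["S1", "S2"]
        assert len(a.schedules) == 4 and len(a.breath_series) == 4
        for key in a.thigh_series:
            for x, y in zip(a.thigh_series[key], b.thigh_series[key]):
                np.testing.assert_array_equal(x.angle, y.angle)
        for key in a.breath_series:
            np.testing.assert_array_equal(a.breath_series[key].vo2, b.breath_series[key].vo2)
        assert a.profiles == b.profiles

    def test_ground_truth_recorded(self):
        cfg = GeneratorConfig(n_days=1, schedule_scale=0.05)
        c = generate_cohort(2, cfg, master_seed=9)
        for prof in c.profiles:
            curve = c.ground_truth[prof.subject_id]
            assert curve.tau == pytest.approx(prof.tau)
            assert curve.cost0 == pytest.approx(prof.cost0)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, GeneratorConfig(n_days=1, schedule_scale=0.05), 0)
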