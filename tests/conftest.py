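"""Shared fixtures: small deterministic profiles, schedules and cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gaitadapt.synthetic_cohort import (
    GeneratorConfig,
    default_schedule,
    generate_profile,
)


@pytest.fixture(scope="session")
def base_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def profile(base_config):
    return generate_profile(base_config, rng_seed=1234)


@pytest.fixture(scope="session")
def noiseless_profile(profile):
    """Profile with every stochastic term switched off."""
    return dataclasses.replace(
        profile,
        var0_sf=0.0,
        varss_sf=0.0,
        var0_mhf=0.0,
        varss_mhf=0.0,
        var0_mhe=0.0,
        varss_mhe=0.0,
        breath_cv=0.0,
        day_drift_sd=0.0,
        stride_period_mean=1.1,
        mhf_mean=30.0,
        mhe_mean=-17.0,
    )


@pytest.fixture(scope="session")
def noiseless_config(base_config) -> GeneratorConfig:
    return dataclasses.replace(
        base_config, sensor_noise_sd=0.0, day_drift_sd=0.0, breath_cv=0.0
    )


@pytest.fixture(scope="session")
def day1_schedule():
    return default_schedule(1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
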