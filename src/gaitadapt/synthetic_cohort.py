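"""Synthetic cohort generator for the six-day exosuit adaptation protocol.

Emulates a small cohort of healthy adults walking on a treadmill at
1.25 m/s while a soft hip exosuit assists hip extension: per day, a quiet
standing trial followed by eight test cycles of alternating no-suit and
with-suit walking blocks, 40 min of with-suit exposure per day over six
days (240 min total).

Two coupled exponential processes drive the signals:

* net with-suit metabolic cost, as a percentage of the same-day no-suit
  baseline, decays as  C(t) = cost_ss + (cost0 - cost_ss) * exp(-t/tau);
* stride-to-stride variability of step frequency, maximum hip flexion
  (MHF) and maximum hip extension (MHE) decays as
  v(t) = varss + (var0 - varss) * exp(-t/tau_var),

where t is cumulative with-suit walking exposure in minutes.  Breath
samples carry multiplicative noise (CV ~ 5%, the intra-individual
fluctuation typically seen in steady-state walking metabolics) and the
no-suit baseline drifts from day to day, which is exactly why downstream
analysis normalizes with-suit cost to the daily no-suit baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    AdaptationCurve,
    Block,
    BreathSeries,
    SessionSchedule,
    SubjectProfile,
    ThighAngleSeries,
)

__all__ = [
    "GeneratorConfig",
    "CohortDataset",
    "variance_at",
    "cost_percent_at",
    "generate_profile",
    "default_schedule",
    "simulate_thigh_angle",
    "simulate_standing_trial",
    "simulate_breath_series",
    "generate_cohort",
]

# Brockway coefficients, W per (ml/s) of O2 / CO2
BROCKWAY_O2 = 16.58
BROCKWAY_CO2 = 4.51
# respiratory exchange ratio used when inverting Brockway to gas volumes
DEFAULT_RER = 0.85
# within-stride waveform: MHF -> MHE over the first 62% of the cycle
# (hip extension phase through stance), MHE -> MHF over the final 38%
DESCENT_FRACTION = 0.62


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling distributions for subject profiles and session structure.

    Means and spreads are chosen to reproduce the study conditions: a
    metabolic time constant of roughly 202 +/- 78 min, Day-1 to Day-6
    variability reductions of order 40-65%, an asymptotic with-suit cost
    10-15% below the no-suit baseline, ~5% breath-level noise, and a few
    percent of day-to-day baseline drift.
    """

    n_days: int = 6
    sample_rate: float = 400.0  # Hz
    speed: float = 1.25  # m/s
    schedule_scale: float = 1.0  # shrinks block durations for smoke tests
    # metabolic adaptation
    tau_mean: float = 202.0  # min
    tau_sd: float = 78.0
    tau_bounds: tuple[float, float] = (40.0, 500.0)
    cost0_mean: float = 101.0  # % of daily no-suit baseline
    cost0_sd: float = 2.0
    cost_drop_mean: float = 16.0  # cost0 - cost_ss, percentage points
    cost_drop_sd: float = 6.0
    cost_drop_bounds: tuple[float, float] = (4.0, 30.0)
    # variability decay; tau_var tracks tau (variability stabilizes on the
    # same time course as the metabolic decay), with lognormal spread
    tau_var_log_sd: float = 0.15
    var0_sf: float = 4.0e-4  # Hz^2
    varss_sf_ratio: float = 0.08
    var0_mhf: float = 2.5  # deg^2
    varss_mhf_ratio: float = 0.45
    var0_mhe: float = 2.0  # deg^2
    varss_mhe_ratio: float = 0.38
    var_log_sd: float = 0.2  # subject-level lognormal spread on var0s
    # anthropometrics & gait
    body_mass_mean: float = 73.42  # kg
    body_mass_sd: float = 9.56
    resting_power_per_kg: float = 1.2  # W/kg, quiet standing
    net_walk_power_per_kg: float = 3.4  # W/kg, no-suit net at 1.25 m/s
    stride_period_mean: float = 1.1  # s
    stride_period_sd: float = 0.05
    mhf_mean: float = 30.0  # deg
    mhf_sd: float = 3.0
    mhe_mean: float = -17.0  # deg
    mhe_sd: float = 3.0
    # noise
    breath_cv: float = 0.05
    day_drift_sd: float = 3.0  # %
    sensor_noise_sd: float = 0.3  # deg, high-pass sensor noise on angle
    breath_interval: tuple[float, float] = (2.0, 5.0)  # s
    # calibration offset of the raw (uncalibrated) thigh angle per day
    calibration_offset_sd: float = 2.0  # deg
    standing_trial_seconds: float = 30.0
    include_nosuit_kinematics: bool = False

    def __post_init__(self) -> None:
        if self.tau_mean <= 0:
            raise ValueError("tau_mean must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    def scaled_noise(self, factor: float) -> "GeneratorConfig":
        """Return a copy with all noise amplitudes scaled by ``factor``."""
        return replace(
            self,
            breath_cv=self.breath_cv * factor,
            day_drift_sd=self.day_drift_sd * factor,
            sensor_noise_sd=self.sensor_noise_sd * factor,
        )


@dataclass
class CohortDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    profiles: list[SubjectProfile]
    schedules: dict  # (subject_id, day) -> SessionSchedule
    thigh_series: dict  # (subject_id, day) -> list[ThighAngleSeries]
    standing_series: dict  # (subject_id, day) -> ThighAngleSeries
    breath_series: dict  # (subject_id, day) -> BreathSeries
    ground_truth: dict  # subject_id -> AdaptationCurve
    day_multipliers: dict  # (subject_id, day) -> float
    config: GeneratorConfig

    @property
    def subject_ids(self) -> list[str]:
        return [p.subject_id for p in self.profiles]


def variance_at(var0: float, varss: float, tau_var: float, t: float) -> float:
    """Variability decay law v(t) = varss + (var0 - varss) * exp(-t/tau)."""
    return varss + (var0 - varss) * math.exp(-t / tau_var)


def cost_percent_at(profile: SubjectProfile, t: float) -> float:
    """Target with-suit cost (% of daily baseline) at exposure ``t`` min."""
    return profile.cost_ss + (profile.cost0 - profile.cost_ss) * math.exp(
        -t / profile.tau
    )


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    max_tries: int = 1000,
) -> float:
    if sd == 0.0:
        return float(np.clip(mean, *bounds))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return float(x)
    raise RuntimeError("truncated-normal sampling did not terminate")


def generate_profile(
    config: GeneratorConfig, rng_seed: int | np.random.Generator, subject_id: str = "S1"
) -> SubjectProfile:
    """Draw one subject profile; resamples until all invariants hold."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    tau = _truncated_normal(rng, config.tau_mean, config.tau_sd, config.tau_bounds)
    tau_var = tau * math.exp(rng.normal(0.0, config.tau_var_log_sd))
    cost0 = rng.normal(config.cost0_mean, config.cost0_sd)
    drop = _truncated_normal(
        rng, config.cost_drop_mean, config.cost_drop_sd, config.cost_drop_bounds
    )
    mass = _truncated_normal(rng, config.body_mass_mean, config.body_mass_sd, (45, 120))
    v0_sf = config.var0_sf * math.exp(rng.normal(0.0, config.var_log_sd))
    v0_mhf = config.var0_mhf * math.exp(rng.normal(0.0, config.var_log_sd))
    v0_mhe = config.var0_mhe * math.exp(rng.normal(0.0, config.var_log_sd))
    mhf = rng.normal(config.mhf_mean, config.mhf_sd)
    mhe = rng.normal(config.mhe_mean, config.mhe_sd)
    if mhf <= mhe:  # ~10 sd apart at defaults; guard for extreme configs
        mhf, mhe = max(mhf, mhe) + 1.0, min(mhf, mhe)
    return SubjectProfile(
        subject_id=subject_id,
        body_mass=mass,
        tau=tau,
        cost0=float(cost0),
        cost_ss=float(cost0 - drop),
        resting_power=config.resting_power_per_kg * mass,
        baseline_net_power=config.net_walk_power_per_kg * mass,
        stride_period_mean=_truncated_normal(
            rng, config.stride_period_mean, config.stride_period_sd, (0.6, 2.0)
        ),
        mhf_mean=float(mhf),
        mhe_mean=float(mhe),
        var0_sf=v0_sf,
        varss_sf=v0_sf * config.varss_sf_ratio,
        var0_mhf=v0_mhf,
        varss_mhf=v0_mhf * config.varss_mhf_ratio,
        var0_mhe=v0_mhe,
        varss_mhe=v0_mhe * config.varss_mhe_ratio,
        tau_var=tau_var,
        day_drift_sd=config.day_drift_sd,
        breath_cv=config.breath_cv,
    )


def default_schedule(
    day_index: int, n_days: int = 6, speed: float = 1.25, scale: float = 1.0
) -> SessionSchedule:
    """Daily session: standing, then 8 cycles of no-suit / rest / with-suit.

    With-suit walking totals 40 min (8 x 5 min); a 5 min mid-session break
    follows the fourth cycle for fatigue recovery.  ``scale`` shrinks all
    block durations proportionally (desk-scale smoke runs only).
    """
    if not (1 <= day_index <= n_days):
        raise ValueError(f"day_index must be in 1..{n_days}, got {day_index}")
    blocks: list[Block] = [Block("standing", 300.0 * scale)]
    for cycle in range(8):
        blocks.append(Block("nosuit", 120.0 * scale))
        blocks.append(Block("rest", 30.0 * scale))
        blocks.append(Block("withsuit", 300.0 * scale))
        blocks.append(Block("rest", (300.0 if cycle == 3 else 30.0) * scale))
    return SessionSchedule(day_index=day_index, blocks=tuple(blocks), speed=speed)


def _stride_parameters(
    profile: SubjectProfile,
    n_strides: int,
    exposure_min: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-stride (period, MHF, MHE) draws at the given exposure stamps."""
    decay = np.exp(-exposure_min / profile.tau_var)
    v_sf = profile.varss_sf + (profile.var0_sf - profile.varss_sf) * decay
    v_mhf = profile.varss_mhf + (profile.var0_mhf - profile.varss_mhf) * decay
    v_mhe = profile.varss_mhe + (profile.var0_mhe - profile.varss_mhe) * decay
    if np.any(v_sf < 0) or np.any(v_mhf < 0) or np.any(v_mhe < 0):
        raise RuntimeError("negative variance in decay schedule")
    freq = 1.0 / profile.stride_period_mean + rng.normal(size=n_strides) * np.sqrt(v_sf)
    freq = np.clip(freq, 0.3, 3.0)
    period = 1.0 / freq
    mhf = profile.mhf_mean + rng.normal(size=n_strides) * np.sqrt(v_mhf)
    mhe = profile.mhe_mean + rng.normal(size=n_strides) * np.sqrt(v_mhe)
    # keep peaks above troughs even in extreme draws
    bad = mhf - mhe < 5.0
    if np.any(bad):
        mid = 0.5 * (mhf[bad] + mhe[bad])
        mhf[bad] = mid + 2.5
        mhe[bad] = mid - 2.5
    return period, mhf, mhe


def _waveform(
    period: np.ndarray,
    mhf: np.ndarray,
    mhe: np.ndarray,
    duration: float,
    rate: float,
) -> np.ndarray:
    """Piecewise half-cosine thigh angle from per-stride parameters.

    Each stride starts at its MHF peak, descends to its MHE trough at
    ``DESCENT_FRACTION`` of the cycle, then rises to the next stride's MHF.
    Band-limited well below 7 Hz at normal cadence, so peaks and troughs
    survive the analysis filter.
    """
    starts = np.concatenate([[0.0], np.cumsum(period)])
    t = np.arange(int(round(duration * rate))) / rate
    t = t[t < starts[-2]] if len(starts) > 2 else t  # need a following MHF
    k = np.searchsorted(starts, t, side="right") - 1
    phase = (t - starts[k]) / period[k]
    angle = np.empty_like(t)
    desc = phase <= DESCENT_FRACTION
    p = phase[desc] / DESCENT_FRACTION
    angle[desc] = mhe[k[desc]] + (mhf[k[desc]] - mhe[k[desc]]) * 0.5 * (
        1 + np.cos(np.pi * p)
    )
    p = (phase[~desc] - DESCENT_FRACTION) / (1 - DESCENT_FRACTION)
    nxt = np.minimum(k[~desc] + 1, len(mhf) - 1)
    angle[~desc] = mhe[k[~desc]] + (mhf[nxt] - mhe[k[~desc]]) * 0.5 * (
        1 - np.cos(np.pi * p)
    )
    return angle


def _highpass_noise(
    n: int, sd: float, rate: float, rng: np.random.Generator, cutoff: float = 12.0
) -> np.ndarray:
    """White sensor noise restricted to frequencies above ``cutoff`` Hz,
    so the analysis low-pass (7 Hz) can remove it completely."""
    from scipy.signal import butter, sosfiltfilt

    if sd == 0.0 or n < 30:
        return np.zeros(n)
    sos = butter(4, cutoff, btype="highpass", fs=rate, output="sos")
    noise = sosfiltfilt(sos, rng.normal(0.0, sd, size=n))
    return noise


def simulate_thigh_angle(
    profile: SubjectProfile,
    schedule: SessionSchedule,
    exposure_offset: float,
    rng_seed: int | np.random.Generator,
    config: GeneratorConfig | None = None,
    calibration_offset: float = 0.0,
) -> list[ThighAngleSeries]:
    """Simulate thigh-angle series for the walking blocks of one session.

    ``exposure_offset`` is cumulative with-suit exposure (min) before the
    session.  The exposure clock advances only inside with-suit blocks;
    no-suit blocks (generated only if the config asks for them) use the
    frozen exposure at their start.  ``calibration_offset`` models the raw
    sensor's deviation from the upright reference, removed downstream by
    standing-trial calibration.
    """
    config = config or GeneratorConfig()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    rate = config.sample_rate
    out: list[ThighAngleSeries] = []
    exposure = exposure_offset
    for idx, block in enumerate(schedule.blocks):
        if block.kind not in ("withsuit", "nosuit"):
            continue
        advance = block.kind == "withsuit"
        if block.kind == "nosuit" and not config.include_nosuit_kinematics:
            continue
        n_strides = int(math.ceil(block.duration / (0.8 * profile.stride_period_mean))) + 2
        approx_t = exposure + (
            np.arange(n_strides) * profile.stride_period_mean / 60.0 if advance else 0.0
        )
        period, mhf, mhe = _stride_parameters(profile, n_strides, np.atleast_1d(approx_t) * np.ones(n_strides), rng)
        angle = _waveform(period, mhf, mhe, block.duration, rate)
        angle = angle + calibration_offset
        angle = angle + _highpass_noise(angle.size, config.sensor_noise_sd, rate, rng)
        out.append(
            ThighAngleSeries(
                angle=angle,
                rate=rate,
                subject_id=profile.subject_id,
                day_index=schedule.day_index,
                block_index=idx,
                block_kind=block.kind,
                exposure_start=exposure,
            )
        )
        if advance:
            exposure += block.duration / 60.0
    return out


def simulate_standing_trial(
    profile: SubjectProfile,
    rng_seed: int | np.random.Generator,
    config: GeneratorConfig | None = None,
    calibration_offset: float = 0.0,
    day_index: int = 1,
) -> ThighAngleSeries:
    """Quiet-standing thigh-angle trial used for the 0-deg calibration."""
    config = config or GeneratorConfig()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    n = int(config.standing_trial_seconds * config.sample_rate)
    angle = np.full(n, calibration_offset) + _highpass_noise(
        n, config.sensor_noise_sd, config.sample_rate, rng
    )
    return ThighAngleSeries(
        angle=angle,
        rate=config.sample_rate,
        subject_id=profile.subject_id,
        day_index=day_index,
        block_index=0,
        block_kind="standing",
    )


def brockway_gas_for_power(
    power_w: np.ndarray, rer: float = DEFAULT_RER
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the Brockway equation at a fixed RER.

    P [W] = 16.58 * vo2[ml/s] + 4.51 * vco2[ml/s] with vco2 = rer * vo2
    gives vo2 [ml/min] = 60 * P / (16.58 + 4.51 * rer).
    """
    vo2 = 60.0 * np.asarray(power_w, dtype=float) / (BROCKWAY_O2 + BROCKWAY_CO2 * rer)
    return vo2, rer * vo2


def simulate_breath_series(
    profile: SubjectProfile,
    schedule: SessionSchedule,
    exposure_offset: float,
    rng_seed: int | np.random.Generator,
    day_multiplier: float = 1.0,
    config: GeneratorConfig | None = None,
) -> BreathSeries:
    """Breath-by-breath V'O2/V'CO2 for one full session.

    Target gross power is resting power during standing and rest blocks,
    ``resting + baseline_net * day_multiplier`` during no-suit walking and
    ``resting + baseline_net * day_multiplier * C(t)/100`` during with-suit
    walking, where C is the subject's cost-decay curve at cumulative
    exposure t.  Each breath carries multiplicative noise with
    CV = ``profile.breath_cv``; gas volumes are back-computed through the
    Brockway equation at a fixed respiratory exchange ratio.
    """
    config = config or GeneratorConfig()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lo, hi = config.breath_interval
    times, powers, b_idx, b_kind = [], [], [], []
    t_session = 0.0
    exposure = exposure_offset
    for idx, block in enumerate(schedule.blocks):
        t = t_session + rng.uniform(lo, hi)
        end = t_session + block.duration
        while t < end:
            if block.kind == "withsuit":
                t_exp = exposure + (t - t_session) / 60.0
                net = (
                    profile.baseline_net_power
                    * day_multiplier
                    * cost_percent_at(profile, t_exp)
                    / 100.0
                )
            elif block.kind == "nosuit":
                net = profile.baseline_net_power * day_multiplier
            else:  # standing / rest
                net = 0.0
            powers.append(profile.resting_power + net)
            times.append(t)
            b_idx.append(idx)
            b_kind.append(block.kind)
            t += rng.uniform(lo, hi)
        if block.kind == "withsuit":
            exposure += block.duration / 60.0
        t_session = end
    power = np.asarray(powers)
    if profile.breath_cv > 0:
        noise = rng.normal(1.0, profile.breath_cv, size=power.size)
        power = power * np.clip(noise, 0.05, None)
    vo2, vco2 = brockway_gas_for_power(power)
    return BreathSeries(
        time=np.asarray(times),
        vo2=vo2,
        vco2=vco2,
        block_index=np.asarray(b_idx, dtype=int),
        block_kind=np.asarray(b_kind, dtype=object),
        subject_id=profile.subject_id,
        day_index=schedule.day_index,
    )


def generate_cohort(
    n_subjects: int = 5,
    config: GeneratorConfig | None = None,
    master_seed: int = 0,
) -> CohortDataset:
    """Generate a complete multi-day cohort with recorded ground truth.

    Per-subject and per-day randomness is drawn from child generators
    spawned deterministically from the master seed, so the dataset is
    reproducible and individual subjects are independent.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    config = config or GeneratorConfig()
    ss = np.random.SeedSequence(master_seed)
    subject_seeds = ss.spawn(n_subjects)
    profiles: list[SubjectProfile] = []
    schedules, thigh, standing, breath, truth, day_mult = {}, {}, {}, {}, {}, {}
    for i, sub_ss in enumerate(subject_seeds):
        sid = f"S{i + 1}"
        streams = [np.random.default_rng(s) for s in sub_ss.spawn(1 + 3 * config.n_days)]
        profile = generate_profile(config, streams[0], subject_id=sid)
        profiles.append(profile)
        truth[sid] = AdaptationCurve(
            cost0=profile.cost0, cost_ss=profile.cost_ss, tau=profile.tau
        )
        exposure = 0.0
        for d in range(1, config.n_days + 1):
            rng_kin, rng_breath, rng_misc = streams[1 + 3 * (d - 1) : 1 + 3 * d]
            sched = default_schedule(
                d, n_days=config.n_days, speed=config.speed, scale=config.schedule_scale
            )
            schedules[(sid, d)] = sched
            mult = float(
                np.clip(rng_misc.normal(1.0, profile.day_drift_sd / 100.0), 0.5, 1.5)
            )
            day_mult[(sid, d)] = mult
            offset = float(rng_misc.normal(0.0, config.calibration_offset_sd))
            standing[(sid, d)] = simulate_standing_trial(
                profile, rng_misc, config, calibration_offset=offset, day_index=d
            )
            thigh[(sid, d)] = simulate_thigh_angle(
                profile, sched, exposure, rng_kin, config, calibration_offset=offset
            )
            breath[(sid, d)] = simulate_breath_series(
                profile, sched, exposure, rng_breath, day_multiplier=mult, config=config
            )
            exposure += sched.withsuit_seconds / 60.0
    return CohortDataset(
        profiles=profiles,
        schedules=schedules,
        thigh_series=thigh,
        standing_series=standing,
        breath_series=breath,
        ground_truth=truth,
        day_multipliers=day_mult,
        config=config,
    )
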