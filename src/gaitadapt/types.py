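"""Domain containers shared across the pipeline.

Conventions used throughout:

* angles are sagittal thigh angles in degrees, flexion positive,
  0 deg = upright standing thigh (after standing-trial calibration);
* ``exposure`` is cumulative *with-suit walking* time in minutes — rest,
  standing and no-suit walking do not advance the exposure clock;
* metabolic cost is net power (gross minus resting) per kg, expressed as a
  percentage of the same day's no-suit baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Block",
    "SessionSchedule",
    "SubjectProfile",
    "ThighAngleSeries",
    "BreathSeries",
    "GaitEvent",
    "GaitCycle",
    "VariabilityWindow",
    "AdaptationCurve",
    "ExponentialFit",
    "FoldResult",
    "EvaluationReport",
]

BLOCK_KINDS = ("standing", "nosuit", "rest", "withsuit")


@dataclass(frozen=True)
class Block:
    """One schedule entry: a block kind and its duration in seconds."""

    kind: str
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("block duration must be positive")


@dataclass(frozen=True)
class SessionSchedule:
    """Ordered block structure of one experimental day.

    The default protocol starts with a quiet-standing trial (resting
    metabolic rate), then alternates no-suit and with-suit walking blocks
    in eight test cycles with short rests, at constant treadmill speed.
    """

    day_index: int
    blocks: tuple[Block, ...]
    speed: float = 1.25  # m/s

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule needs at least one block")
        if self.blocks[0].kind != "standing":
            raise ValueError("schedule must begin with a standing block")

    def blocks_of(self, kind: str) -> list[tuple[int, Block]]:
        return [(i, b) for i, b in enumerate(self.blocks) if b.kind == kind]

    @property
    def withsuit_seconds(self) -> float:
        return sum(b.duration for b in self.blocks if b.kind == "withsuit")

    @property
    def total_seconds(self) -> float:
        return sum(b.duration for b in self.blocks)


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters of one synthetic participant.

    ``tau`` (min) is the metabolic adaptation time constant; ``tau_var``
    the decay constant shared by the three variability features.  Costs
    are percentages of the daily no-suit net baseline.  Variances are the
    initial / steady-state stride-to-stride variances of step frequency
    (Hz^2) and of the per-stride maximum hip flexion / extension angles
    (deg^2).
    """

    subject_id: str
    body_mass: float  # kg
    tau: float  # min of cumulative with-suit exposure
    cost0: float  # % of daily no-suit baseline at t = 0
    cost_ss: float  # asymptotic %
    resting_power: float  # W
    baseline_net_power: float  # W, no-suit net walking power
    stride_period_mean: float  # s
    mhf_mean: float  # deg
    mhe_mean: float  # deg
    var0_sf: float
    varss_sf: float
    var0_mhf: float
    varss_mhf: float
    var0_mhe: float
    varss_mhe: float
    tau_var: float  # min
    day_drift_sd: float  # % spread of the daily baseline multiplier
    breath_cv: float  # CV of breath-level multiplicative noise

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.tau_var <= 0:
            raise ValueError("time constants must be positive")
        if not (self.cost0 >= self.cost_ss > 0):
            raise ValueError("require cost0 >= cost_ss > 0")
        for v0, vss in (
            (self.var0_sf, self.varss_sf),
            (self.var0_mhf, self.varss_mhf),
            (self.var0_mhe, self.varss_mhe),
        ):
            if v0 < 0 or vss < 0 or v0 < vss:
                raise ValueError("variances must satisfy var0 >= varss >= 0")
        if self.stride_period_mean <= 0:
            raise ValueError("stride_period_mean must be positive")
        if self.mhf_mean <= self.mhe_mean:
            raise ValueError("mhf_mean must exceed mhe_mean")
        if self.body_mass <= 0 or self.resting_power <= 0:
            raise ValueError("mass and resting power must be positive")


@dataclass
class ThighAngleSeries:
    """Uniformly sampled sagittal thigh angle for one block.

    ``angle`` holds the samples (deg); time is implicit — sample ``i`` is
    at ``start_time + i / rate`` seconds (block-local clock).
    """

    angle: np.ndarray
    rate: float  # Hz
    subject_id: str = ""
    day_index: int = 0
    block_index: int = 0
    block_kind: str = "withsuit"
    exposure_start: float = 0.0  # cumulative with-suit minutes at block start
    start_time: float = 0.0

    @property
    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.angle.size) / self.rate

    @property
    def duration(self) -> float:
        return self.angle.size / self.rate

    def replace_angle(self, angle: np.ndarray) -> "ThighAngleSeries":
        out = ThighAngleSeries(
            angle=np.asarray(angle, dtype=float),
            rate=self.rate,
            subject_id=self.subject_id,
            day_index=self.day_index,
            block_index=self.block_index,
            block_kind=self.block_kind,
            exposure_start=self.exposure_start,
            start_time=self.start_time,
        )
        return out


@dataclass
class BreathSeries:
    """Breath-by-breath gas exchange for one session (one day)."""

    time: np.ndarray  # s, strictly increasing, session clock
    vo2: np.ndarray  # ml/min
    vco2: np.ndarray  # ml/min
    block_index: np.ndarray  # schedule block each breath falls in
    block_kind: np.ndarray  # kind label per breath
    subject_id: str = ""
    day_index: int = 0

    def __post_init__(self) -> None:
        if np.any(self.vo2 < 0) or np.any(self.vco2 < 0):
            raise ValueError("gas volumes must be non-negative")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("breath times must be strictly increasing")


@dataclass(frozen=True)
class GaitEvent:
    time: float
    angle: float
    kind: str  # "mhf" or "mhe"


@dataclass(frozen=True)
class GaitCycle:
    """One MHF-to-MHF stride."""

    start_time: float  # s, block-local
    stride_time: float  # s
    mhf_angle: float  # deg
    mhe_angle: float  # deg
    exposure_time: float  # cumulative with-suit minutes at cycle start
    subject_id: str = ""
    day_index: int = 0
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.stride_time <= 0:
            raise ValueError("stride_time must be positive")
        if self.mhf_angle <= self.mhe_angle:
            raise ValueError("mhf_angle must exceed mhe_angle")

    @property
    def step_frequency(self) -> float:
        # literal inverse of the MHF-to-MHF stride time
        return 1.0 / self.stride_time


@dataclass(frozen=True)
class VariabilityWindow:
    """Variance triple over a fixed run of consecutive gait cycles."""

    var_sf: float  # Hz^2
    var_mhf: float  # deg^2
    var_mhe: float  # deg^2
    exposure_time: float  # min, mean cycle exposure in the window
    window_index: int
    subject_id: str = ""
    day_index: int = 0

    def features(self) -> np.ndarray:
        return np.array([self.var_sf, self.var_mhf, self.var_mhe])


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting v(t) = vss + (v0 - vss) * exp(-t / tau)."""

    v0: float
    vss: float
    tau: float
    r2: float
    converged: bool
    ci95: dict | None = None  # per-parameter (lo, hi)


@dataclass(frozen=True)
class AdaptationCurve:
    """Fitted exponential metabolic-cost decay defining ground truth.

    Adaptation level is the inverse of the decay,
    A(t) = 100 * (1 - exp(-t / tau)), reaching 100% at the plateau.
    """

    cost0: float
    cost_ss: float
    tau: float
    fit_r2: float = 1.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def cost(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.cost_ss + (self.cost0 - self.cost_ss) * np.exp(
            -np.asarray(t, dtype=float) / self.tau
        )


@dataclass
class FoldResult:
    test_subject: str
    band_accuracy: float  # %
    mae: float  # percentage points
    pearson_r: float
    r2: float
    n_windows: int
    converged: bool = True
    note: str = ""


@dataclass
class EvaluationReport:
    per_fold: list[FoldResult] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)  # metric -> (mean, sd)
    indicators: dict = field(default_factory=dict)
    ttests: list[dict] = field(default_factory=list)
    curves: dict = field(default_factory=dict)  # subject -> AdaptationCurve

    def to_dict(self) -> dict:
        return {
            "per_fold": [vars(f) for f in self.per_fold],
            "pooled": {k: list(v) for k, v in self.pooled.items()},
            "indicators": self.indicators,
            "ttests": self.ttests,
            "curves": {
                s: {
                    "cost0": c.cost0,
                    "cost_ss": c.cost_ss,
                    "tau": c.tau,
                    "fit_r2": c.fit_r2,
                    "converged": c.converged,
                }
                for s, c in self.curves.items()
            },
        }
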