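"""Metabolic cost and the exponential adaptation ground truth.

Gross metabolic power comes from breath-by-breath gas exchange through
the Brockway equation; net walking cost is gross power minus the quiet-
standing resting power, per kg.  With-suit cost is normalized to the same
day's no-suit baseline (cancelling day-to-day physiological drift) and
the resulting (exposure, cost%) points are fit with

    C(t) = cost_ss + (cost0 - cost_ss) * exp(-t / tau),

t in cumulative with-suit minutes.  Adaptation level is the inverse of
that decay, A(t) = 100 * (1 - exp(-t / tau)), 100% at the plateau; a
subject counts as adapted once C(t) comes within 5% of the asymptotic
value.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from ._fitting import fit_exponential_decay
from .types import AdaptationCurve, BreathSeries, SessionSchedule, VariabilityWindow

__all__ = [
    "brockway_power",
    "block_cost",
    "normalize_daily",
    "session_costs",
    "fit_adaptation_curve",
    "adaptation_level",
    "time_to_adaptation",
    "ground_truth_labels",
]

log = logging.getLogger(__name__)

BROCKWAY_O2 = 16.58  # W per ml/s of O2
BROCKWAY_CO2 = 4.51  # W per ml/s of CO2
METABOLIC_TAIL_MINUTES = 2.0  # steady-state tail averaged per walking block
ADAPTATION_BAND = 0.05  # "within 5% of the asymptotic value"


def brockway_power(vo2, vco2):
    """Gross metabolic power (W) from V'O2 and V'CO2 in ml/min.

    P = 16.58 * (vo2/60) + 4.51 * (vco2/60); accepts scalars or arrays.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 < 0) or np.any(vco2 < 0):
        raise ValueError("gas volumes must be non-negative")
    out = BROCKWAY_O2 * vo2 / 60.0 + BROCKWAY_CO2 * vco2 / 60.0
    return float(out) if out.ndim == 0 else out


def block_cost(
    series: BreathSeries,
    block_index: int,
    resting_power: float,
    body_mass: float,
    tail_minutes: float = METABOLIC_TAIL_MINUTES,
) -> float | None:
    """Net metabolic cost (W/kg) of one walking block's steady-state tail.

    Averages Brockway power over the block's final ``tail_minutes``,
    subtracts resting power and divides by body mass.  Returns None when
    the block does not contain the full tail (missing-value signal).
    """
    mask = series.block_index == block_index
    if not np.any(mask):
        return None
    t = series.time[mask]
    block_end = t[-1]
    block_start = t[0]
    if block_end - block_start < tail_minutes * 60.0 - 10.0:
        # allow a few seconds of slack for breath discretization
        log.debug("block %d shorter than %g min tail", block_index, tail_minutes)
        return None
    tail = t >= block_end - tail_minutes * 60.0
    p = brockway_power(series.vo2[mask][tail], series.vco2[mask][tail])
    return (float(np.mean(p)) - resting_power) / body_mass


def normalize_daily(ws_cost: float, ns_cost: float) -> float:
    """With-suit cost as a percentage of the daily no-suit baseline."""
    if ns_cost <= 0:
        raise ValueError("no-suit baseline cost must be positive")
    return 100.0 * ws_cost / ns_cost


def session_costs(
    series: BreathSeries,
    schedule: SessionSchedule,
    resting_power: float,
    body_mass: float,
    exposure_offset: float,
    tail_minutes: float = METABOLIC_TAIL_MINUTES,
) -> list[tuple[float, float]]:
    """(exposure_min, normalized cost %) per with-suit block of one day.

    The daily no-suit baseline is the mean net cost across the day's
    no-suit blocks; each with-suit block contributes one point stamped
    with the cumulative exposure at the centre of its averaged tail.
    """
    ns_costs = [
        c
        for idx, _ in schedule.blocks_of("nosuit")
        if (c := block_cost(series, idx, resting_power, body_mass, tail_minutes))
        is not None
    ]
    if not ns_costs:
        raise ValueError("no usable no-suit baseline block in session")
    baseline = float(np.mean(ns_costs))
    points: list[tuple[float, float]] = []
    exposure = exposure_offset
    for idx, block in enumerate(schedule.blocks):
        if block.kind != "withsuit":
            continue
        cost = block_cost(series, idx, resting_power, body_mass, tail_minutes)
        if cost is not None:
            tail_centre = exposure + (block.duration / 60.0) - tail_minutes / 2.0
            points.append((tail_centre, normalize_daily(cost, baseline)))
        exposure += block.duration / 60.0
    return points


def fit_adaptation_curve(costs: list[tuple[float, float]]) -> AdaptationCurve:
    """Fit the exponential cost decay over all sessions jointly.

    ``costs`` holds (exposure_min, cost_percent) points, at least 6 and
    ideally spanning several sessions.  Multistart nonlinear least squares
    with tau bounded to (1, 1e4) min; non-convergence is flagged on the
    returned curve rather than raised.
    """
    if len(costs) < 6:
        raise ValueError("need at least 6 cost points spanning multiple sessions")
    t = np.array([c[0] for c in costs])
    y = np.array([c[1] for c in costs])
    fit = fit_exponential_decay(t, y)
    if not fit.converged or not np.isfinite(fit.tau):
        return AdaptationCurve(
            cost0=float(y[0]),
            cost_ss=float(y[-1]),
            tau=max(t.max(), 1.0),
            fit_r2=fit.r2,
            converged=False,
        )
    return AdaptationCurve(
        cost0=fit.v0, cost_ss=fit.vss, tau=fit.tau, fit_r2=fit.r2, converged=True
    )


def adaptation_level(curve: AdaptationCurve, t) -> float | np.ndarray:
    """A(t) = 100 * (1 - exp(-t / tau)), the inverse of the cost decay.

    0% at first exposure, approaching 100% at the asymptotic plateau.
    """
    if not curve.converged:
        raise ValueError("adaptation level requires a converged curve fit")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("exposure time must be non-negative")
    out = 100.0 * (1.0 - np.exp(-t_arr / curve.tau))
    return float(out) if out.ndim == 0 else out


def time_to_adaptation(
    curve: AdaptationCurve, band: float = ADAPTATION_BAND, mode: str = "asymptote"
) -> float:
    """Exposure (min) at which the cost enters the adaptation band.

    ``mode='asymptote'`` (default): the band is ``band * cost_ss`` — the
    smallest t with C(t) - cost_ss <= 0.05 * cost_ss, i.e.
    t* = tau * ln((cost0 - cost_ss) / (band * cost_ss)).
    ``mode='amplitude'``: the band is a fraction of the decay amplitude,
    t* = tau * ln(1 / band) (95% of the decay completed).
    Returns 0 when the cost is already within the band at t = 0.
    """
    if not curve.converged:
        raise ValueError("time to adaptation requires a converged curve fit")
    amplitude = curve.cost0 - curve.cost_ss
    if amplitude <= 0:
        log.info("cost0 <= cost_ss: no decay, already adapted at t=0")
        return 0.0
    if mode == "asymptote":
        threshold = band * curve.cost_ss
        if amplitude <= threshold:
            return 0.0
        return curve.tau * math.log(amplitude / threshold)
    if mode == "amplitude":
        return curve.tau * math.log(1.0 / band)
    raise ValueError("mode must be 'asymptote' or 'amplitude'")


def ground_truth_labels(
    curve: AdaptationCurve, windows: list[VariabilityWindow]
) -> np.ndarray:
    """Adaptation level evaluated at each window's exposure stamp."""
    if not windows:
        return np.empty(0)
    t = np.array([w.exposure_time for w in windows])
    return np.asarray(adaptation_level(curve, t))
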