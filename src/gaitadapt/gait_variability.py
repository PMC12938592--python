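"""Windowed gait-variability features and their decay fits.

The three adaptation indicators are the sample variances of step
frequency, MHF angle and MHE angle over non-overlapping windows of 10
consecutive gait cycles, stamped with cumulative with-suit exposure.
Session-level summaries use the final 3 min of with-suit walking of each
day; their Day-1 to Day-6 percent reduction and the exponential decay fit
v(t) = vss + (v0 - vss) * exp(-t / tau_var) quantify stabilization of the
gait pattern with practice.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np

from ._fitting import fit_exponential_decay
from .types import ExponentialFit, GaitCycle, VariabilityWindow

__all__ = [
    "windowed_variance",
    "build_feature_windows",
    "steady_state_summary",
    "percent_reduction",
    "fit_indicator_decay",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 10
FEATURES = ("sf", "mhf", "mhe")


def windowed_variance(values: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Sample variance (ddof=1) over consecutive non-overlapping windows.

    Trailing cycles that do not fill a complete window are dropped; a
    series shorter than one window yields an empty result.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    values = np.asarray(values, dtype=float)
    n_win = values.size // window
    if n_win == 0:
        log.debug("series of %d values shorter than window %d", values.size, window)
        return np.empty(0)
    return values[: n_win * window].reshape(n_win, window).var(axis=1, ddof=1)


def build_feature_windows(
    cycles: list[GaitCycle], window: int = DEFAULT_WINDOW
) -> list[VariabilityWindow]:
    """Align the three variances over the same runs of 10 cycles.

    Windows never span a block boundary (and hence never a rest break):
    cycles are grouped by (day, block) and windowed within each group, in
    chronological order.  Each window's exposure stamp is the mean cycle
    exposure inside it.
    """
    groups: dict[tuple, list[GaitCycle]] = defaultdict(list)
    for c in cycles:
        groups[(c.subject_id, c.day_index, c.block_index)].append(c)
    windows: list[VariabilityWindow] = []
    idx = 0
    for key in sorted(groups):
        cyc = sorted(groups[key], key=lambda c: c.start_time)
        sf = np.array([c.step_frequency for c in cyc])
        mhf = np.array([c.mhf_angle for c in cyc])
        mhe = np.array([c.mhe_angle for c in cyc])
        exp = np.array([c.exposure_time for c in cyc])
        n_win = sf.size // window
        for w in range(n_win):
            sl = slice(w * window, (w + 1) * window)
            windows.append(
                VariabilityWindow(
                    var_sf=float(np.var(sf[sl], ddof=1)),
                    var_mhf=float(np.var(mhf[sl], ddof=1)),
                    var_mhe=float(np.var(mhe[sl], ddof=1)),
                    exposure_time=float(exp[sl].mean()),
                    window_index=idx,
                    subject_id=key[0],
                    day_index=key[1],
                )
            )
            idx += 1
    return windows


def steady_state_summary(
    windows: list[VariabilityWindow], minutes: float = 3.0
) -> dict[str, float] | None:
    """Mean variance triple over the final ``minutes`` of with-suit walking.

    ``windows`` should be one session's (one day's) windows; the steady
    state is taken as those whose exposure stamp falls within ``minutes``
    of the session's last window.  Returns None when no window qualifies.
    """
    if not windows:
        return None
    end = max(w.exposure_time for w in windows)
    tail = [w for w in windows if w.exposure_time >= end - minutes]
    if not tail:
        return None
    return {
        "sf": float(np.mean([w.var_sf for w in tail])),
        "mhf": float(np.mean([w.var_mhf for w in tail])),
        "mhe": float(np.mean([w.var_mhe for w in tail])),
        "n_windows": len(tail),
    }


def percent_reduction(day1: float, day6: float) -> float:
    """100 * (day1 - day6) / day1; negative when the value increased."""
    if day1 <= 0:
        raise ValueError("day-1 reference must be positive")
    return 100.0 * (day1 - day6) / day1


def fit_indicator_decay(
    windows: list[VariabilityWindow], feature: str
) -> ExponentialFit:
    """Exponential decay fit of one indicator across a subject's windows.

    Nonlinear least squares of v(t) = vss + (v0 - vss) * exp(-t/tau_var)
    with multistart initialization over the time constant; returns the
    fit with a 95% CI from the parameter covariance and an R^2 diagnostic.
    Non-identifiable input (e.g. constant series) is flagged, not raised.
    """
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    t = np.array([w.exposure_time for w in windows])
    y = np.array([getattr(w, f"var_{feature}") for w in windows])
    return fit_exponential_decay(t, y)
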