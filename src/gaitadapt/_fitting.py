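"""Shared exponential-decay fitting with multistart initialization.

Both the metabolic-cost curve and the variability indicators follow
y(t) = yss + (y0 - yss) * exp(-t / tau).  tau is poorly conditioned when
the data span less than one time constant, so the fit is restarted from
several tau guesses and the least-SSE solution is kept.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import curve_fit

from .types import ExponentialFit

__all__ = ["fit_exponential_decay"]

TAU_STARTS = (30.0, 100.0, 200.0, 400.0)  # min
TAU_BOUNDS = (1.0, 1.0e4)  # min


def _model(t: np.ndarray, y0: float, yss: float, tau: float) -> np.ndarray:
    return yss + (y0 - yss) * np.exp(-t / tau)


def fit_exponential_decay(
    t: np.ndarray,
    y: np.ndarray,
    tau_starts: tuple[float, ...] = TAU_STARTS,
    tau_bounds: tuple[float, float] = TAU_BOUNDS,
) -> ExponentialFit:
    """Least-squares fit of yss + (y0 - yss) * exp(-t / tau).

    Returns a flagged (non-converged) result instead of raising when the
    data cannot identify the parameters (constant series, all fits
    failing); tau is bounded to (1, 1e4) min.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size:
        raise ValueError("t and y must have equal length")
    if t.size < 4:
        raise ValueError("need at least 4 points to fit 3 parameters")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < 1e-300 * max(1.0, float(np.abs(y).max()) ** 2) or np.ptp(y) == 0.0:
        # constant series: tau unidentifiable
        return ExponentialFit(
            v0=float(y[0]), vss=float(y[0]), tau=np.nan, r2=0.0, converged=False
        )
    scale = max(float(np.abs(y).max()), 1e-12)
    lo = [-10.0 * scale, -10.0 * scale, tau_bounds[0]]
    hi = [10.0 * scale, 10.0 * scale, tau_bounds[1]]
    best = None
    for tau0 in tau_starts:
        p0 = [float(y[0]), float(y[-1]), float(np.clip(tau0, *tau_bounds))]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _model, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((y - _model(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return ExponentialFit(
            v0=float(y[0]), vss=float(y[-1]), tau=np.nan, r2=0.0, converged=False
        )
    sse, popt, pcov = best
    r2 = 1.0 - sse / sst
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    names = ("v0", "vss", "tau")
    ci = {
        n: (float(p - 1.96 * s), float(p + 1.96 * s))
        for n, p, s in zip(names, popt, se)
    }
    # a tau pinned to its bounds with an unbounded CI is not identifiable
    tau_ok = np.isfinite(se[2]) or (tau_bounds[0] * 1.01 < popt[2] < tau_bounds[1] * 0.99)
    return ExponentialFit(
        v0=float(popt[0]),
        vss=float(popt[1]),
        tau=float(popt[2]),
        r2=float(r2),
        converged=bool(tau_ok),
        ci95=ci,
    )
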