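"""Thigh-angle signal conditioning and gait-cycle segmentation.

The raw input is the sagittal-plane thigh angle sampled at 400 Hz by a
thigh-mounted IMU.  Processing follows standard practice for wearable
gait analysis:

1. calibrate against a quiet-standing trial so 0 deg is the upright thigh;
2. zero-phase low-pass filter at 7 Hz to strip sensor noise while keeping
   the kinematic content of walking;
3. detect per-stride extrema — maximum hip flexion (MHF, peak) and
   maximum hip extension (MHE, trough);
4. segment MHF-to-MHF strides into :class:`~gaitadapt.types.GaitCycle`
   records carrying stride time, the two extremal angles and the cycle's
   cumulative with-suit exposure stamp.

Stride time is the interval between successive same-leg MHF events and
"step frequency" is its literal inverse (this follows the source data's
convention; note it is a stride-based rate, not a step-based one).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .types import GaitCycle, GaitEvent, ThighAngleSeries

__all__ = [
    "calibrate_standing",
    "lowpass",
    "detect_events",
    "segment_cycles",
    "process_block",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 7.0  # Hz
MIN_PROMINENCE = 5.0  # deg, guards against residual ripple
MIN_STANDING_SECONDS = 1.0


def calibrate_standing(
    series: ThighAngleSeries, standing: ThighAngleSeries
) -> ThighAngleSeries:
    """Re-reference the angle so 0 deg is the upright standing thigh.

    Subtracts the mean angle of the quiet-standing trial; metadata is
    preserved.  The standing trial must be at least 1 s long (>= 5 s of
    quiet standing is recommended).
    """
    if standing.duration < MIN_STANDING_SECONDS:
        raise ValueError(
            f"standing trial too short ({standing.duration:.2f} s < "
            f"{MIN_STANDING_SECONDS} s)"
        )
    offset = float(np.mean(standing.angle))
    return series.replace_angle(series.angle - offset)


def lowpass(series: ThighAngleSeries, cutoff: float = DEFAULT_CUTOFF) -> ThighAngleSeries:
    """Zero-phase 4th-order Butterworth low-pass filter.

    Forward-backward filtering keeps event timing unbiased, which matters
    because stride-time variance is a downstream feature.  Passband
    sinusoids below ``cutoff / 2`` are preserved in amplitude to within 1%.
    """
    nyquist = series.rate / 2.0
    if not (0 < cutoff < nyquist):
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    sos = butter(4, cutoff, btype="lowpass", fs=series.rate, output="sos")
    return series.replace_angle(sosfiltfilt(sos, series.angle))


def _median_period_samples(angle: np.ndarray, rate: float) -> float | None:
    """Provisional stride period (samples) from a prominence-only pass."""
    peaks, _ = find_peaks(angle, prominence=MIN_PROMINENCE)
    if len(peaks) < 3:
        return None
    return float(np.median(np.diff(peaks)))


def _refine_by_template(
    angle: np.ndarray, idx: np.ndarray, period: float, slack: int = 16
) -> np.ndarray:
    """Matched-filter refinement of event sample indices.

    Noise that survives the low-pass filter sits in the same band as the
    gait signal and can move a flat extremum by several samples.  Cross-
    correlating each event's neighbourhood with the block's mean event
    template re-times the event using the steep mid-stride slopes, which
    carry far more timing information than the extremum itself.
    """
    if len(idx) < 3:
        return idx
    # window spans one full period so the (asymmetric) stride waveform is
    # periodic across the window edges; a shorter window biases the
    # correlation argmax away from true alignment
    w = int(round(0.5 * period))
    keep = (idx >= w + slack) & (idx < angle.size - w - slack)
    if keep.sum() < 3:
        return idx
    inner = idx[keep]
    template = np.mean([angle[i - w : i + w] for i in inner], axis=0)
    template = template - template.mean()
    shifts = np.arange(-slack, slack + 1)
    segments = np.stack([angle[i - w - slack : i + w + slack] for i in inner])
    segments = segments - segments.mean(axis=1, keepdims=True)
    scores = np.stack(
        [segments[:, s + slack : s + slack + 2 * w] @ template for s in shifts],
        axis=1,
    )
    refined = idx.copy()
    refined[keep] = inner + shifts[np.argmax(scores, axis=1)]
    return refined


def detect_events(
    series: ThighAngleSeries,
    min_prominence: float = MIN_PROMINENCE,
    refine: bool = True,
) -> list[GaitEvent]:
    """Locate alternating MHF (peak) / MHE (trough) events.

    Local-extremum search with a minimum inter-peak distance of half the
    median provisional stride period and a minimum prominence of 5 deg,
    followed (by default) by matched-filter timing refinement against the
    block's mean stride template.  Events are forced to strictly
    alternate: within any run of same-kind events only the most extreme
    one is kept.  Fewer than two MHF events yields an empty list (no
    cycles), not an error.
    """
    angle = series.angle
    med = _median_period_samples(angle, series.rate)
    if med is None:
        return []
    distance = max(1, int(0.5 * med))
    peaks, _ = find_peaks(angle, prominence=min_prominence, distance=distance)
    troughs, _ = find_peaks(-angle, prominence=min_prominence, distance=distance)
    if len(peaks) < 2:
        return []
    if refine:
        peaks = _refine_by_template(angle, peaks, med)
        troughs = _refine_by_template(angle, troughs, med)
    events = sorted(
        [(int(i), "mhf") for i in peaks] + [(int(i), "mhe") for i in troughs]
    )
    # enforce alternation: keep the extremal event of each same-kind run
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = angle[idx] > angle[prev] if kind == "mhf" else angle[idx] < angle[prev]
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    t0 = series.start_time
    return [
        GaitEvent(time=t0 + i / series.rate, angle=float(angle[i]), kind=k)
        for i, k in kept
    ]


def segment_cycles(
    events: list[GaitEvent],
    exposure_start: float = 0.0,
    accumulate_exposure: bool = True,
    subject_id: str = "",
    day_index: int = 0,
    block_index: int = 0,
) -> list[GaitCycle]:
    """Build one :class:`GaitCycle` per consecutive MHF pair.

    ``exposure_start`` is the cumulative with-suit exposure (min) at the
    block's first sample; each cycle is stamped with the exposure at its
    own start (frozen when ``accumulate_exposure`` is False, e.g. for
    no-suit blocks).  A cycle whose intermediate trough is missing is
    dropped and logged.
    """
    mhf_idx = [i for i, e in enumerate(events) if e.kind == "mhf"]
    cycles: list[GaitCycle] = []
    if len(mhf_idx) < 2:
        return cycles
    block_t0 = events[mhf_idx[0]].time if events else 0.0
    # block-local time of the first event's sample is its own time minus
    # the series start; callers pass series with start_time=0 per block
    for a, b in zip(mhf_idx[:-1], mhf_idx[1:]):
        start, end = events[a], events[b]
        between = [e for e in events[a + 1 : b] if e.kind == "mhe"]
        if not between:
            log.debug("dropping cycle at t=%.3f s: no MHE between MHF pair", start.time)
            continue
        trough = min(between, key=lambda e: e.angle)
        stride_time = end.time - start.time
        elapsed_min = (start.time - block_t0) / 60.0 if accumulate_exposure else 0.0
        cycles.append(
            GaitCycle(
                start_time=start.time,
                stride_time=stride_time,
                mhf_angle=start.angle,
                mhe_angle=trough.angle,
                exposure_time=exposure_start + elapsed_min,
                subject_id=subject_id,
                day_index=day_index,
                block_index=block_index,
            )
        )
    return cycles


def process_block(
    series: ThighAngleSeries,
    standing: ThighAngleSeries | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[GaitCycle]:
    """Calibrate (optional), filter and segment one walking block."""
    s = calibrate_standing(series, standing) if standing is not None else series
    s = lowpass(s, cutoff)
    events = detect_events(s)
    return segment_cycles(
        events,
        exposure_start=series.exposure_start,
        accumulate_exposure=series.block_kind == "withsuit",
        subject_id=series.subject_id,
        day_index=series.day_index,
        block_index=series.block_index,
    )
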