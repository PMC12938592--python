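"""CSV / YAML interchange for pipeline stages.

Schemas:

* block CSV — ``time_s, thigh_angle_deg`` (one walking block, 400 Hz);
* breath CSV — ``time_s, vo2_ml_min, vco2_ml_min`` (one session);
* cycles CSV — ``subject, day, block, start_time_s, stride_time_s,
  step_freq_hz, mhf_deg, mhe_deg, exposure_min``;
* features CSV — ``subject, day, window_index, exposure_min, var_sf_hz2,
  var_mhf_deg2, var_mhe_deg2``;
* labels CSV — ``subject, window_index, exposure_min,
  adaptation_true_pct``;
* cohort manifest YAML — subjects, days, block files/kinds and the
  generator's ground-truth curve parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metabolic_adaptation import time_to_adaptation
from .types import (
    BreathSeries,
    GaitCycle,
    ThighAngleSeries,
    VariabilityWindow,
)

__all__ = [
    "write_block_csv",
    "read_block_csv",
    "write_breath_csv",
    "write_cycles_csv",
    "read_cycles_csv",
    "write_features_csv",
    "read_features_csv",
    "write_labels_csv",
    "write_curves_json",
    "write_cohort",
]


def write_block_csv(path, series: ThighAngleSeries) -> None:
    pd.DataFrame({"time_s": series.time, "thigh_angle_deg": series.angle}).to_csv(
        path, index=False
    )


def read_block_csv(path, **meta) -> ThighAngleSeries:
    """Load a block CSV; sampling rate is inferred from the time column."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: time must be strictly increasing")
    if np.ptp(dt) > 1e-6:
        raise ValueError(f"{path}: sampling must be uniform (jitter > 1e-6 s)")
    return ThighAngleSeries(
        angle=df["thigh_angle_deg"].to_numpy(dtype=float),
        rate=1.0 / float(np.mean(dt)),
        start_time=float(t[0]),
        **meta,
    )


def write_breath_csv(path, series: BreathSeries) -> None:
    pd.DataFrame(
        {
            "time_s": series.time,
            "vo2_ml_min": series.vo2,
            "vco2_ml_min": series.vco2,
            "block_index": series.block_index,
            "block_kind": series.block_kind,
        }
    ).to_csv(path, index=False)


def write_cycles_csv(path, cycles_by_subject: dict[str, list[GaitCycle]]) -> None:
    rows = [
        {
            "subject": c.subject_id,
            "day": c.day_index,
            "block": c.block_index,
            "start_time_s": c.start_time,
            "stride_time_s": c.stride_time,
            "step_freq_hz": c.step_frequency,
            "mhf_deg": c.mhf_angle,
            "mhe_deg": c.mhe_angle,
            "exposure_min": c.exposure_time,
        }
        for cycles in cycles_by_subject.values()
        for c in cycles
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cycles_csv(path) -> dict[str, list[GaitCycle]]:
    df = pd.read_csv(path)
    out: dict[str, list[GaitCycle]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject), []).append(
            GaitCycle(
                start_time=row.start_time_s,
                stride_time=row.stride_time_s,
                mhf_angle=row.mhf_deg,
                mhe_angle=row.mhe_deg,
                exposure_time=row.exposure_min,
                subject_id=str(row.subject),
                day_index=int(row.day),
                block_index=int(row.block),
            )
        )
    return out


def write_features_csv(path, windows_by_subject: dict[str, list[VariabilityWindow]]) -> None:
    rows = [
        {
            "subject": w.subject_id,
            "day": w.day_index,
            "window_index": w.window_index,
            "exposure_min": w.exposure_time,
            "var_sf_hz2": w.var_sf,
            "var_mhf_deg2": w.var_mhf,
            "var_mhe_deg2": w.var_mhe,
        }
        for windows in windows_by_subject.values()
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features_csv(path) -> dict[str, list[VariabilityWindow]]:
    df = pd.read_csv(path)
    out: dict[str, list[VariabilityWindow]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.subject), []).append(
            VariabilityWindow(
                var_sf=row.var_sf_hz2,
                var_mhf=row.var_mhf_deg2,
                var_mhe=row.var_mhe_deg2,
                exposure_time=row.exposure_min,
                window_index=int(row.window_index),
                subject_id=str(row.subject),
                day_index=int(row.day),
            )
        )
    return out


def write_labels_csv(path, sequences, windows_by_subject) -> None:
    rows = []
    for seq in sequences:
        windows = windows_by_subject[seq.subject_id]
        for w, label in zip(windows, seq.labels):
            rows.append(
                {
                    "subject": seq.subject_id,
                    "window_index": w.window_index,
                    "exposure_min": w.exposure_time,
                    "adaptation_true_pct": label,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_curves_json(path, curves: dict, band_mode: str = "asymptote") -> None:
    payload = {
        sid: {
            "cost0_pct": c.cost0,
            "cost_ss_pct": c.cost_ss,
            "tau_min": c.tau,
            "r2": c.fit_r2,
            "converged": c.converged,
            "time_to_adaptation_min": (
                time_to_adaptation(c, mode=band_mode) if c.converged else None
            ),
        }
        for sid, c in curves.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_cohort(out_dir, cohort) -> Path:
    """Dump a generated cohort to per-block CSVs plus a manifest YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": []}
    for profile in cohort.profiles:
        sid = profile.subject_id
        entry: dict = {
            "subject_id": sid,
            "body_mass_kg": profile.body_mass,
            "ground_truth": {
                "tau_min": profile.tau,
                "cost0_pct": profile.cost0,
                "cost_ss_pct": profile.cost_ss,
                "tau_var_min": profile.tau_var,
            },
            # assistive-force profile timing, recorded as metadata only
            "assist_timing_pct_gait_cycle": {"onset": 4, "peak": 28, "release": 42},
            "days": [],
        }
        for d in range(1, cohort.config.n_days + 1):
            day_dir = out / sid / f"day{d}"
            day_dir.mkdir(parents=True, exist_ok=True)
            standing = cohort.standing_series[(sid, d)]
            write_block_csv(day_dir / "standing.csv", standing)
            blocks = []
            for series in cohort.thigh_series[(sid, d)]:
                name = f"block{series.block_index:02d}_{series.block_kind}.csv"
                write_block_csv(day_dir / name, series)
                blocks.append(
                    {
                        "file": str(Path(sid) / f"day{d}" / name),
                        "kind": series.block_kind,
                        "block_index": series.block_index,
                        "exposure_start_min": series.exposure_start,
                    }
                )
            write_breath_csv(day_dir / "breath.csv", cohort.breath_series[(sid, d)])
            entry["days"].append(
                {
                    "day": d,
                    "standing": str(Path(sid) / f"day{d}" / "standing.csv"),
                    "breath": str(Path(sid) / f"day{d}" / "breath.csv"),
                    "blocks": blocks,
                }
            )
        manifest["subjects"].append(entry)
    with open(out / "cohort.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out / "cohort.yaml"
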