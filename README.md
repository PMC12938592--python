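# gaitadapt

Tools for studying how people adapt to a soft hip exosuit during
multi-day treadmill walking, and for estimating that adaptation in real
time from wearable sensor data alone.

When a wearable robot starts assisting hip extension, walking is at
first *less* economical: the user has to learn to exploit the
assistance.  Metabolic cost — measured by indirect calorimetry and
normalized to a same-day no-suit baseline — decays exponentially with
cumulative exposure time,

    C(t) = cost_ss + (cost0 − cost_ss) · e^(−t/τ),

and the **adaptation level** is the inverse of that decay,
A(t) = 100 · (1 − e^(−t/τ)), reaching 100 % at the plateau.  Measuring
C(t) requires a respiratory gas analyzer, which is impractical outside
the lab.  The package's central question is whether *gait variability* —
the stride-to-stride variances of step frequency, maximum hip flexion
(MHF) and maximum hip extension (MHE), computed from a thigh-mounted
IMU over windows of 10 gait cycles — can stand in for the metabolic
ground truth: variability also settles exponentially as the user adapts,
and an LSTM trained on the variability windows can emit an adaptation
estimate every 10 strides, causally, with no metabolic hardware.

The package covers the full analysis chain, each stage usable on its
own:

| module | what it does |
|---|---|
| `synthetic_cohort` | generates a 5-subject, 6-day protocol (40 min/day of with-suit walking in 8 blocks alternating with no-suit walking and rests, at 1.25 m/s): 400 Hz thigh-angle signals, breath-by-breath gas exchange, ground-truth curves |
| `imu_kinematics` | standing-trial calibration, zero-phase 7 Hz low-pass, MHF/MHE event detection with matched-filter re-timing, stride segmentation |
| `gait_variability` | windowed variance features, steady-state summaries, Day-1→Day-6 reductions, exponential decay fits |
| `metabolic_adaptation` | Brockway power, daily-baseline normalization, adaptation-curve fitting, adaptation-level labels |
| `adaptation_estimator` | the LSTM regressor (NumPy implementation: BPTT, Adam, early stopping) with amortized training on a fitted decay family |
| `evaluation_protocol` | leave-one-subject-out evaluation: ±10-point band accuracy, MAE, Pearson r, R², paired t-tests |
| `pipeline` / `cli` | end-to-end orchestration and the `gaitadapt` command |

## Worked example

```python
from gaitadapt.pipeline import PipelineConfig, run_pipeline
from gaitadapt.synthetic_cohort import GeneratorConfig

result = run_pipeline(PipelineConfig(
    n_subjects=5, master_seed=1,
    generator=GeneratorConfig().scaled_noise(0.5),  # half measurement noise
    eval_seeds=(1, 2, 3),
))
m = result.metabolic
print(f"metabolic reduction Day1→Day6: {m['reduction_mean']:.1f} ± {m['reduction_sd']:.1f} %"
      f"  (paired t p = {m['p']:.4f})")
print(f"adaptation time constant: {m['tau_mean']:.0f} ± {m['tau_sd']:.0f} min")
for f, d in result.indicators["per_feature"].items():
    print(f"variability reduction {f}: {d['reduction_mean']:.1f} ± {d['reduction_sd']:.1f} %")
band = [r.pooled["band_accuracy"][0] for r in result.reports]
print(f"LOSO band accuracy (mean over 3 training seeds): {sum(band)/3:.1f} %")
```

Output on the seeds above:

```
metabolic reduction Day1→Day6: 10.9 ± 3.9 %  (paired t p = 0.0023)
adaptation time constant: 181 ± 95 min
variability reduction sf: 65.2 ± 10.7 %
variability reduction mhf: 36.2 ± 2.0 %
variability reduction mhe: 36.7 ± 13.5 %
LOSO band accuracy (mean over 3 training seeds): 34.1 %
```

Reading the numbers: with-suit walking becomes ~11 % cheaper over six
days relative to the daily no-suit baseline, with a time constant of
roughly three hours of cumulative exposure; step-frequency variability
drops by about two-thirds and the hip-angle variabilities by over a
third, on the same time course.  The cross-validated estimator places
34 % of its per-window estimates within ±10 percentage points of the
held-out subject's metabolic adaptation curve on this particular cohort
draw — cross-subject accuracy depends strongly on the cohort, because
the reference labels are *fitted* curves: for a subject whose time
constant approaches the protocol length the fit overshoots, and that
subject's labels are then unpredictable from gait features alone, which
caps leave-one-subject-out accuracy no matter the model.  On other
cohort draws the same pipeline reaches ~69 % (see
`docs/methods.md` for the structural analysis).

The same run from a shell:

```sh
gaitadapt run-all --out out/ --seed 1 --eval-seeds 1,2,3
```

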