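# gaitwalker

Analytics for a sensor-instrumented rehabilitation walker: quantifying
bilateral load asymmetry, simulating the closed-loop vibrotactile feedback
that corrects it, detecting walker instability from tri-axial acceleration,
tracking neuromuscular engagement with surface EMG, modeling rehabilitation
trajectories with Gaussian Process Regression, and comparing stride-time
variability between groups. It is written for rehabilitation-engineering and
biomedical-signal researchers who want the full analysis chain of such a
device as tested, seedable Python — no hardware required.

## The models

**Force symmetry.** Each handle carries a force sensor; the Robinson-style
Force Symmetry Index of the right/left forces is

    FSI = |F_R − F_L| / (F_R + F_L) ∈ [0, 1]

(0 = perfect symmetry, 1 = one-handed loading). A session is summarized by
the FSI of its mean forces; a program by per-day FSI trajectories and the
improvement `100·(FSI_day1 − FSI_day15)/FSI_day1`. When the instantaneous
FSI exceeds a calibrated threshold, a 300 ms vibration pulse on the heavier
side cues the user to unload it.

**Trajectory modeling.** Pooled force-sensor series are modeled with a
Gaussian process, y(x) ~ GP(m, k) with constant mean and RBF kernel
k(x,x′) = σ_f² exp(−(x−x′)²/2l²) plus observation noise σ_n²;
hyperparameters (σ_f², l, σ_n²) maximize the log marginal likelihood

    log p(y|x,θ) = −½ yᵀ(K+σ_n²I)⁻¹y − ½ log|K+σ_n²I| − (n/2) log 2π,

giving predictive means with 95% bands. The GP is implemented from first
principles (Cholesky with escalating jitter, multi-start L-BFGS on
log-parameters, analytic gradients) and pinned by dense-algebra oracles.

**Signals.** sEMG is band-passed (30–500 Hz, zero-phase Butterworth,
overall order 4), wavelet-denoised (db4, hybrid SureShrink), and summarized
as mean rectified amplitude in mV; Day-1 vs Day-15 cohort amplitudes are
compared with a paired t-test. Walker orientation is classified from the
gravity direction (tilt arccos(a_z/|a|); upright / inclined / falling with
a free-fall magnitude override) with debounced alerts. Stride times come
from peak detection with transient filtering; groups are compared by
variance ratio and a median-centered Levene test.

Because the study deposits no recordings, a seeded generator
(`gaitwalker.synth`) produces multimodal streams calibrated to the published
cohort statistics; every analysis is validated against it. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```
python analysis/02_symmetry_report.py --seed 0 --out results
```

prints the per-subject symmetry table recomputed through the generation →
session-FSI → cohort-summary path (noise off, so generation targets are
recovered exactly):

```
Subject       Day 1 FSI  Day 15 FSI  Improvement %
--------------------------------------------------
Subject 1        0.9526      0.1530          83.94
Subject 2        0.9800      0.1129          88.48
...
Subject 10       0.8949      0.1630          81.79
--------------------------------------------------
Mean             0.9691      0.2019          79.26
```

i.e. the cohort's mean asymmetry falls from 0.9691 to 0.2019 over the
15-day program — a 79.26% mean reduction. The other drivers follow the same
pattern; with `--seed 0` they print, for example:

```
analysis/05_emg_analysis.py   activation change dEMG = 4.185 mV, t(9) = 15.41, p = 8.90e-08
analysis/04_fall_detection.py seeded suite: sensitivity 50/50, false alarms 0
analysis/06_gpr_trajectory.py fsr1: chronological-forecast R^2 = 0.8505; random-split R^2 = 0.9917
analysis/07_stride_variability.py ratio = 9.00 (larger: als_like), p = 6.43e-40
```

The EMG change is the processed cohort's Day-15 − Day-1 mean rectified
amplitude (positive and strongly significant); the GP numbers contrast the
hard forecasting regime (predicting the final, steepest days) with the
interpolation regime; the stride ratio is ALS-like vs control variance.
`01_simulate_cohort.py` materializes the raw CSV streams, and
`03_feedback_simulation.py` writes the haptic event log (cohort event
totals collapse from 1990 on day 1 to 397 on day 15 as symmetry recovers).

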