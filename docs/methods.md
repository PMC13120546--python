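# Methods

`gaitwalker` implements the analytics of a sensor-instrumented rehabilitation
walker: bilateral handlebar force sensing with closed-loop vibrotactile
feedback, accelerometer-based walker-instability detection, surface-EMG
monitoring, Gaussian-process modeling of rehabilitation trajectories, and
stride-time variability analysis. Because no raw recordings accompany the
study, every stage is driven by a seeded synthetic generator whose targets
are the published cohort statistics. This note records the models, the
defaults and why, the numerical choices, and what the synthetic validation
does and does not establish.

## Force symmetry

The central quantity is the Robinson-style Force Symmetry Index of the
right/left handle forces,

    FSI = |F_R − F_L| / (F_R + F_L) ∈ [0, 1],

0 for perfect symmetry, 1 when one hand carries the whole load. A day is
summarized by the FSI *of the session-mean forces* rather than the mean of
per-sample FSIs: the ratio of means is robust to instantaneous near-zero
loads (where the per-sample index is undefined or wildly noisy) and yields
the single per-day value the trajectory plots require. Samples with both
channels below a 0.5 N contact floor are excluded as non-contact; FSI is
undefined at zero total load and the code raises rather than silently
returning 0. Improvement is `100·(FSI_day1 − FSI_day15)/FSI_day1`; this
definition reproduces the published per-subject improvement column exactly,
so it is treated as the implicit reporting convention. Report tables round
half-up to 4 decimals (FSI) and 2 decimals (percent).

ADC counts (10-bit, 0–1023) map to newtons by piecewise-linear
interpolation through a reference-load calibration curve, with clamped
extrapolation beyond the calibrated range; the default curve is mildly
saturating, as thin-film force sensors read through a voltage divider are.

## Recovery trajectory

The published per-subject endpoints (Day 1, Day 15) leave the between-day
path free. The package uses an exponential-in-time trajectory with
*accelerating* progress,

    FSI(d) = f1 − (f1 − f15) · (e^{kτ} − 1)/(e^k − 1),  τ = (d−1)/(n−1),

with k = 1.5791713167283 calibrated once to the three printed Subject-1
values (0.953, 0.752, 0.153 at days 1, 7, 15). A *saturating* exponential
decay cannot pass through the day-7 anchor, which lies above the linear
chord: in this cohort most of the improvement arrives late. A `linear`
shape is also available per subject. The same progress curve interpolates
each subject's EMG amplitude between its Day-1 and Day-15 targets.

## Synthetic data generator

The generator defines the study conditions; all randomness derives from a
single master seed through per-stream sub-seeds (master, CRC32(subject),
day, modality), so identical configurations are bit-reproducible.

* **Force streams** (50 Hz, 60 s sessions): F_R = B(1+s)m(t),
  F_L = B(1−s)m(t) with per-hand scale B = 40 N, target FSI s for the day,
  and a shared positive gait-phase modulation m(t) = 1 + 0.25 sin(2π·0.9t).
  Because m(t) is common to both channels it cancels in the ratio, so the
  zero-noise session FSI equals the target *exactly* — the published table
  is reproduced to all four printed decimals through the analysis path.
  Additive Gaussian sensor noise (sd 1.0 N, truncated at zero) leaves the
  noisy Day-1 cohort mean within ±0.02 of the published 0.9691. ADC columns
  are derived through the inverse calibration curve and clipped to [0, 1023].
* **sEMG** (2 kHz): amplitude-modulated filtered white noise — the standard
  surrogate — with the carrier concentrated at 60–350 Hz (the physiological
  sEMG power band, comfortably inside the 30–500 Hz processing band so the
  documented filtering does not re-attenuate band-edge shoulders) and a
  phasic envelope (one activation burst per gait cycle over a near-silent
  baseline, as in gait EMG). The clean trace is rescaled so its mean
  rectified amplitude equals the day target exactly. Contamination is
  additive: <5 Hz drift (default peak 0.3 mV) and >600 Hz noise (default sd
  0.1 mV). Per-subject Day-1/Day-15 amplitude targets carry a fixed
  zero-sum spread (~15% CV at day 1, ~20% at day 15; larger late spread
  reflects heterogeneous training response) so the cohort means equal the
  published 0.885 and 5.138 mV exactly.
* **Accelerometer** (100 Hz): gravity-dominated tri-axial signal; each
  walker state pins the tilt (upright 0°, inclined 25°, falling 75°), each
  falling segment opens with a 0.3 s free-fall magnitude transient
  (|a| → 0.3 g), Gaussian axis noise (default 0.03 g). Ground-truth segment
  transition times are returned for detector validation.
* **Stride intervals**: footfall times t_i = i·μ + ε_i with ε_i i.i.d.
  N(0, σ²); successive differences then have variance 2σ². Defaults:
  control μ = 1.1 s, σ = 0.02 s; ALS-like μ = 1.4 s, σ = 0.06 s (slower,
  markedly more variable gait).
* **Pooled FSR series** for trajectory modeling: 1200 samples per channel
  over the program, r_right = (1+s̄)/2, r_left = (1−s̄)/2 with s̄(τ) the
  across-subject mean FSI trajectory (channels converge toward 0.5), plus
  observation noise sd 0.01 of the normalized full scale (≈10 counts of a
  10-bit converter; also consistent with subject-level noise at the printed
  RMSE scale averaged over ten subjects).

What the generator does *not* emulate: within-day learning, missing
sessions, electrode-placement drift, real FSR hysteresis and creep,
correlated bilateral noise, or any musculoskeletal mechanism behind the
asymmetry. Passing tests therefore establish that the analytics recover
known structure under the stated noise models — not that the hardware would
reproduce the published numbers.

## Haptic feedback loop

The trigger statistic is the per-sample FSI (normalized difference), making
the trigger insensitive to total load; a raw-difference mode (|F_R − F_L|
in newtons) is available by configuration since the hardware convention is
not documented. The universal threshold is the arithmetic mean of a bench
calibration set (5 testers × 100 varying-load instances; the seeded default
yields ≈0.356). An event opens at the first sample whose statistic exceeds
the threshold, is assigned to the *heavier* side (cueing the user to unload
it), and that side is refractory until its 300 ms pulse window ends —
matching the fixed-duration pulse and bounding the event rate at
⌈session/0.3 s⌉. Stimulus parameters (100 Hz, 1.5 g) are carried as
metadata only; simulated sense-to-actuation latency is one sample period
plus 25 ms, within the 120 ms budget. Event counts are monotone in the
threshold and per-side windows never overlap (property-tested).

## Fall detection

Tilt is referenced to the device z-axis (z up, right-handed):
θ = arccos(a_z/|a|). Axes are low-pass filtered (2nd-order Butterworth,
2 Hz, zero-phase) before classification to isolate gravity from gait-impact
spikes. Classification: falling if θ ≥ 60° or |a| < 0.5 g (free-fall
floor), inclined if θ ≥ 15°, else upright; thresholds are engineering
choices validated on the synthetic suite (sensitivity 50/50, zero false
alarms at axis noise 0.03 g). One alert is emitted per contiguous falling
episode persisting ≥ 200 ms (debounce). The module flags *walker*
instability; it does not detect or predict user falls.

## sEMG processing

A zero-phase Butterworth band-pass, 30–500 Hz, overall order 4 (designed at
order 2 and applied forward–backward), removes drift and high-frequency
noise. Denoising is wavelet-based: Daubechies-4, 4 levels, soft
thresholding, noise scale σ from the MAD of the finest details. The
per-level threshold is the **hybrid SureShrink** rule (SURE-minimizing
threshold on dense levels, universal σ√(2 ln N) fallback on sparse ones).
A plain universal threshold was evaluated and rejected: on dense,
noise-like muscle activity it shrinks the signal itself, *reducing* SNR on
known-SNR fixtures and biasing rectified amplitude by tens of percent,
which would corrupt the longitudinal statistic the pipeline exists to
measure. With the hybrid rule, clean-burst reconstruction error is ≈2% and
SNR strictly improves on contaminated fixtures.

"Mean EMG amplitude" is the mean rectified value of the denoised trace
(RMS is reported as a secondary metric). The Day-15 vs Day-1 comparison is
a two-sided paired t-test, t = mean(d)/(sd(d)/√n), df = n−1, with normal
Q-Q pairs (plotting positions (i−0.5)/n) provided for the distributional
check. With ten subjects df = 9; the synthetic cohort yields a strongly
significant positive change (p < 10⁻⁶), qualitatively matching the study.
The printed per-subject amplitudes are not available, so the printed t
value itself is not a reproducible target; note also the study's printed
ΔEMG (4.28 mV) differs slightly from the difference of its printed means
(5.138 − 0.885 = 4.253 mV) — the package reports the computed difference.

## Gaussian process regression

Written from first principles (no GP library): constant mean m (the
training-output average), RBF kernel k(x,x′) = σ_f² exp(−(x−x′)²/2l²),
observation noise σ_n². Predictions use the standard conditioning
equations; hyperparameters maximize the log marginal likelihood via
L-BFGS-B in log-parameter space with analytic gradients and 8 seeded
log-uniform restarts (data-scaled ranges, plus one heuristic start). All
solves go through Cholesky factorization with escalating jitter
(0 → 10⁻¹⁰ → 10⁻⁸ → 10⁻⁶ of the diagonal scale); an unfactorizable matrix
raises a numerical error naming the hyperparameters. Constant outputs are
handled as a degenerate case (σ_f² at its floor; predictions equal the
constant). Latent predictive variance is clipped at zero and bounded by
σ_f²; 95% bands are observation-level (include σ_n²) so they envelop noisy
data. Correctness is pinned by dense-inverse/determinant oracles (10
significant digits for n ≤ 20), the noiseless-interpolation and
prior-reversion limits (10⁻⁸), an independent reference implementation
(scikit-learn, fixed hyperparameters) and a 20-seed parameter-recovery
simulation at n = 200 (median parameters within a few percent of truth).

The two FSR channels are modeled as independent GPs on the pooled series
(x = sample index). Evaluation uses an 80/20 **chronological** split —
train on the earliest samples, forecast the remainder — because forecasting
the rest of a rehabilitation trajectory is the stated use; 5-fold
cross-validation uses contiguous blocks of the time-ordered series for the
same reason. A caveat this package makes explicit: with a late-accelerating
trajectory the held-out tail is the steepest segment, and a 3-day forecast
of it is intrinsically harder than the interpolation regime that
random-split accuracies reflect. At the default conditions the
chronological-forecast R² is ≈0.85–0.93 per channel while the random-split
R² is ≈0.99; the analysis driver reports both. Problem sizes: recovery
simulation n = 200 × 20 seeds; trajectory fits n = 960 training points,
dense Cholesky.

## Stride variability

Gait cycles are segmented by peak detection (minimum period 0.4 s,
prominence ≥ 0.3 of the signal range — typical human stride constraints);
transient filtering drops the first and last detected cycles and gates
intervals at median ± 3 scaled MADs (removing double-spike and missed-beat
artifacts; an exact-periodicity tolerance keeps noise-free fixtures
intact). Stride-time variability is the unbiased sample variance of the
intervals. Groups are compared by the ratio of group-mean variances plus a
median-centered Levene test on the pooled intervals — robust to the
non-normal stride distributions typical of pathological gait. An external
interval table (subject_id, group, interval_s CSV) can be analyzed in place
of simulation.

## Pipeline and provenance

`pipeline.run_pipeline` executes simulate → symmetry → feedback → falls →
EMG → GPR → stride, writing every stage artifact (fixed CSV schemas:
force `timestamp_s,adc_right,adc_left,f_right_n,f_left_n`; accel
`timestamp_s,ax_g,ay_g,az_g`; emg `timestamp_s,emg_mv`; intervals
`subject_id,group,interval_s`) plus one consolidated JSON report carrying a
hash of the analytic configuration and the master seed; reports contain no
timestamps and are byte-identical across runs with the same seed. A stage
failure aborts with the stage name. Stream files are structurally
validated (columns, monotone timestamps, ADC/force/interval ranges) with
row-indexed errors. The EMG stage processes the program endpoints (days 1
and n) per subject — the days entering the paired test — at 10 s per record
(2 s in the smoke configuration); the smoke configuration also shortens
force sessions to 5 s and the pooled series to 240 points, purely to keep
the default artifact light. The numbered `analysis/` scripts are the
interface for end-to-end runs; the library functions behind them are the
module surface.

## Known limitations

* All validation is against the synthetic generator's assumptions; no
  hardware, no real subjects, no external dataset ships with the package.
* The GP is dense (O(n³)); fine for n ≈ 10³, not for streaming use.
* The fall module classifies walker orientation states only.
* Between-day trajectory shape beyond the three printed anchors, the
  haptic side-assignment, and the FSR resistance-to-force convention are
  design choices documented above, not measured facts.
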