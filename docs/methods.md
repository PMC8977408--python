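# Methods

`myofuse` implements a task-invariant pipeline that continuously estimates
hip, knee and ankle angles and angular velocities from surface
electromyography (EMG) features, sonomyography (B-mode ultrasound intensity)
features, and their fusion, using Gaussian process regression (GPR) with a
rational quadratic kernel, evaluated by leave-one-stride-out
cross-validation over five ambulation tasks (level, 10° incline and 10°
decline walking, stair ascent, stair descent). Because no public recordings
of this kind exist, the package ships a synthetic-data generator whose
outputs carry the statistical structure the analysis assumes, with known
latent ground truth, so every stage is testable end to end.

## Feature extraction

**Surface EMG.** Raw 1,200 Hz signals are mean-centred and band-pass
filtered 20–450 Hz with a design-order-4 Butterworth filter applied
zero-phase (forward–backward). Filtering is zero-phase because the pipeline
is offline and the features must not lag the kinematics; the residual DC
from edge effects is re-removed so channel means are exactly zero. A 200 ms
analysis window advancing by 50 ms then yields a 20 Hz stream of six
features per muscle — mean absolute value, zero crossings, slope sign
changes, waveform length (all with an optional deadband, default 0), and the
first two coefficients of a fourth-order autoregressive model — 48 features
per time point for eight muscles. AR coefficients use the Burg estimator
(stable on 240-sample windows) under the convention
x_t ≈ Σ_k a_k x_{t−k}. Timestamps follow the window-end convention so the
stream is causal if ever run online.

The window advance deserves a note: a "50 ms overlap" of 200 ms windows
would give a 6.67 Hz stream, which is inconsistent with the 20 Hz feature
rate this feature set is conventionally run at; the package resolves the
ambiguity in favour of the 20 Hz rate (50 ms advance, i.e. 150 ms overlap).

**Sonomyography.** Each grayscale frame is tiled into non-overlapping
3 × 3 mm blocks anchored at the superficial-left corner; trailing partial
blocks at the deep/right edges are discarded so every feature averages a
full block. The block-mean grid is flattened row-major (superficial rows
first) and complemented by a temporal feature, the frame-to-frame time
derivative of each block mean (units: intensity/s; the first frame's
temporal half is zero so the stream stays frame-aligned). Under the default
geometry — 60 mm axial × 39 mm lateral at 0.5 mm/pixel, i.e. 120 × 78
pixels — the grid is 20 × 13 = 260 blocks and the combined feature set is
520 per frame. The axial depth matches a typical 6 cm thigh penetration
depth; the lateral extent is reverse-engineered from the 520-feature total
and remains configurable, as does the 20 Hz frame rate chosen so ultrasound
frames pair 1:1 with the EMG feature clock.

## Synchronization, strides, pooling

The common clock is the 20 Hz EMG feature clock restricted to the temporal
overlap of the three streams: sonomyography features are mapped to each tick
by nearest frame time (ties to the earlier frame), kinematics (100 Hz) are
linearly interpolated down. Heel-strike events — ground truth from the
generator, or a JSON file for external data; no gait-event detection is
implemented — split rows into strides (stride i = ticks in
[hs_i, hs_{i+1})); intervals with fewer than 4 rows are discarded with a
warning. Strides from all tasks are pooled into one task-invariant table per
modality; **fusion is column concatenation of the sonomyography then EMG
features** (568 columns). Standardization statistics are deliberately not
computed at pooling time: they are derived inside each model fit from
training rows only, and an audit re-checks this on every fold.

## Regression model

One independent GP per kinematic target (6 per modality). The covariance is
the rational quadratic kernel

k(x,x′) = σ²(1 + r²/(2αl²))^(−α),  r² = (x−x′)ᵀ(x−x′),

with amplitude σ, scale-mixture parameter α (α→∞ recovers the squared
exponential with length-scale l) and fitted observation-noise SD. The
exponent −α is the standard form of this kernel and is implemented as such.
The mean function is the training-target mean (zero after target
standardization), the conventional default. Hyperparameters are fitted by
maximizing the log marginal likelihood in log-parameter space with analytic
gradients (L-BFGS-B, gradient and step tolerances 10⁻³, three seeded
restarts; box bounds keep the search numerically safe, including a noise
floor of 10⁻³ on the standardized scale). Features and target are z-scored
from the training rows; zero-variance columns get unit scale.

Two data-size controls keep fits tractable: above a block size of 1,000
observations the model trains on a seeded subset that large (a
blocked/subset stance toward large-n fitting; exact dense inference is used
below it because it is strictly more accurate at desk scale), and the
marginal-likelihood search itself runs on a seeded subset of at most 400
rows — a standard subset-of-data approximation justified because
hyperparameters are far smoother functionals of the data than the posterior
mean. Predictions always use the full (or block-capped) training set through
a cached Cholesky solve and are exact posterior means, de-standardized to
output units. A tiny jitter (10⁻¹⁰) stabilizes the factorization.

## Evaluation

Leave-one-stride-out folds: fold i holds out the i-th stride of every task
that has at least i+1 strides; the fold count is the largest per-task stride
count, every stride tests exactly once, and all remaining strides train.
This is one consistent reading of leave-one-stride-out with unequal per-task
stride counts (walking trials contribute more strides than short stair
bouts).

Metrics per (modality, target, task): RMSE over all of that task's held-out
predictions, nRMSE = 100·RMSE/range of the measured series, and adjusted
R² = 1 − (N−1)/(N−1−p)·(1−R²) with R² = 1 − SS_res/SS_tot, where p is the
number of feature columns of the modality (48, 520 or 568) and N is the
training-row count (the mean across folds, since folds differ by one stride).
If N−1−p ≤ 0 the adjusted R² is undefined and reported as NaN. The
"overall" row is the unweighted mean of the five task values. Modalities are
compared by one-way ANOVA on per-replicate overall RMSE values (the
synthetic stand-in for a per-subject design) with Tukey–Kramer pairwise
follow-ups (the unequal-n form) run only when the group effect is
significant at α = 0.05.

## Synthetic data: what it emulates and what it does not

Each task has a stride-periodic template: smooth low-order Fourier joint
profiles affinely mapped onto physiologic per-task ranges (so ranges are
exact by construction and knee profiles differ across tasks), and
non-negative periodic activation profiles (von Mises bumps) for ten latent
muscles — the eight EMG-recorded muscles plus vastus medialis and vastus
intermedius, which the anterior transducer images but EMG does not. A fixed
shape table plus a small seeded jitter makes templates deterministic per
(task, seed) yet distinct across seeds.

A trial realizes the template on a jittered stride clock (default stride
duration SD 5%), with per-stride, per-muscle activation gains (default SD
0.2) as the stride-to-stride physiological variability. Generated signals:

* **Kinematics (100 Hz):** template angle + coupling term + Gaussian noise
  (default SD 0.5°, small but non-degenerate, as in overlaid-stride plots of
  real gait); angular velocity is the numerical time derivative of the noisy
  angle, which realistically makes velocity targets noisier than angles.
* **EMG (1,200 Hz):** the standard phenomenological surface-EMG model —
  band-limited (20–450 Hz) unit-variance carrier noise amplitude-modulated
  by the latent activation — extended with a recruitment-like spectral
  shift: the carrier is a mixture of 20–150 Hz and 150–450 Hz noise whose
  balance moves toward the high band as activation rises. Without that
  shift, the rate-based features (zero crossings, slope sign changes, AR
  coefficients) of a pure amplitude-modulated carrier would carry no
  information at all, which real EMG contradicts. A small measurement-noise
  floor (default 0.2% of channel gain) keeps silent channels non-degenerate.
* **Ultrasound (20 Hz):** a static speckle-like texture (SD 8 intensity
  units) plus per-frame noise (SD 4), with three horizontal bands
  (superficial→deep: RF, VM, VI; the anterior placement) whose brightness
  adds 80·activation, clipped to [0, 255]. At zero noise the block mean in a
  band is an exactly monotone function of its muscle's activation.

**The designed reason fusion helps:** per-stride activation gains perturb
joint angles through a joint-by-muscle coupling matrix whose default gives
every joint a component carried by an imaging-only latent (VM or VI: hip 6°
via VI, knee 8°/6° via VM/VI, ankle 4° via VM per unit gain deviation) and
gives the hip and ankle additional components via EMG-only muscles (TFL 6°,
SOL 5°). Neither modality alone observes all kinematic variability, so
fused models dominate both — the structure the evaluation's ordering tests
assert.

What the generator does **not** emulate: speckle physics and scan
conversion, fascicle/pennation geometry, motor-unit structure, crosstalk,
electrode or probe motion artifact, subject anthropometry, and transition
strides. Consequently, passing tests show the pipeline recovers kinematics
when its modelling assumptions hold and that the fusion-versus-EMG ordering
follows from the designed information structure; they do not certify error
magnitudes on real recordings. In particular, the synthetic image carries
only three informative bands, so sonomyography alone can rank *worse* than
EMG here even though richer real B-mode texture ranked better in vivo.

## Problem sizes and numerical choices

Default dataset: 15 strides per walking task and 8 per stair task
(reproducing the walking/stair imbalance of treadmill bouts versus short
staircases), ≈1,600 pooled 20 Hz rows, 15 folds. The replicated
fusion-versus-EMG comparison runs ten seeded replicates at 5 walking / 3
stair strides per task — the same noise and coupling conditions at a size
chosen so several hundred GP fits complete in minutes on one CPU. Ties,
degenerate inputs and edge cases: zero-variance targets are rejected;
constant EMG windows return zero AR coefficients with a warning; all-zero
feature rows short-circuit; nearest-frame ties resolve to the earlier frame;
strides shorter than 4 clock ticks are dropped with a warning.

## Known limitations

Single isotropic length-scale across 568 heterogeneous columns (no automatic
relevance determination); no predictive-variance reporting; subset-of-data
hyperparameter search can differ from full-likelihood optima on very
heterogeneous folds; the fold rule for unequal stride counts is one of
several defensible readings; heel strikes must be supplied (no event
detection); the synthetic ultrasound is deliberately simple, as above.
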