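# Methods

This note documents the models, numerical choices and limitations behind
`errorfields`. The package simulates and analyzes *error-field* (EF)
training: haptic error augmentation in which the torque applied to a mover
is weighted by the likelihood of the current error under that individual's
own error statistics, so that repeatable errors are amplified and
rare/spurious ones are left alone.

## Task geometry and reference kinematics

The task is a planar goal-directed reach between two on-screen targets
15 cm apart, with an ideal duration `td = 1.5 s`. The display plots
shoulder rotation against elbow flexion/extension, so cursor position is an
affine image (cm/rad scale plus offset, default 10 cm/rad) of the two
joint angles; all quantities in the package live in this screen plane, in
centimeters. The ideal movement is a straight line traversed with the
minimum-jerk profile

    x(t) = x0 + (xT − x0)(10 s³ − 15 s⁴ + 6 s⁵),   s = t/td,

which starts and ends at rest. Evaluation clamps `t` to `[0, td]`: beyond
the ideal duration the reference rests on the target, which avoids the
violent extrapolation of the quintic. Deviations from the reference are
resolved into a signed *extent* component along the start-to-target unit
vector `û` (positive toward/past the target) and a signed *perpendicular*
component along the counter-clockwise normal `n̂`. The sign convention is
the package's own choice — any fixed convention works, but it must be
pinned for the statistics to be reproducible. The decomposition is an
isometry (`extent² + perpendicular² = |ε|²`), which the tests verify.

The default protocol uses three movement directions at headings 0°, 120°
and 240° from a common start. The direction set is a free design choice;
evenly spaced headings give balanced excitation of the visuomotor map and
make the per-direction error statistics genuinely different under the
default distortion. The default sampling rate is 100 Hz (typical
robot-logging rate; configurable via `dt`).

## Error statistics and the likelihood field

Characterization uses the transformed trials of the intermittent-exposure
phase only: those trials show the subject's naive response to the
distortion, before training. Per direction `d` and component
`i ∈ {extent, perpendicular}`:

1. each trial's error samples are assigned to a 50-bin uniform time grid
   over `[0, td]` by nearest sample time;
2. the across-trial mean and standard deviation (ddof = 1) are computed in
   each bin;
3. degree-7 polynomials are least-squares fitted to the mean and SD curves.

Two numerical choices matter. Time is rescaled to `[0, 1]` before fitting —
degree-7 monomial fits on raw seconds are badly conditioned — and the
evaluated SD is floored at `sigma_floor = 0.05 cm`. The floor exists
because the Gaussian density divides by σ: a subject who happens to be
extremely consistent at some instant would otherwise produce an unbounded
density and the torque cap would have to absorb the blow-up alone. The SD
polynomial is fitted unconstrained and floored at evaluation time, not
constrained positive during the fit. Fifty bins comfortably over-determine
an 8-coefficient fit; the bin count is configurable.

The likelihood is a *per-component scalar* Gaussian,

    p(ε) = exp(−(ε − μ_{d,t,i})² / 2σ²_{d,t,i}) / (σ_{d,t,i} √(2π)),

i.e. extent and perpendicular errors carry separate 1-D densities rather
than one joint 2-D density. The model is symmetric about μ by
construction; skewed or multi-modal error distributions, and
re-characterization as training progresses, are out of scope.

## Torque controllers

All controllers act in the extent/perpendicular frame (mapping to physical
joint torques through a manipulator Jacobian is out of scope):

- `NULL`: zero torque (control condition).
- `EA` (error augmentation): `τ = λ ε`, componentwise.
- `EF` (error field): `τ_i = λ p_i(ε_i) ε_i` — each component weighted by
  its own density, so the field tempers augmentation of improbable errors
  and `τ → 0` as `|ε − μ| → ∞`.

Every emitted torque is gated to the first 1.5 s of the movement (so the
mover can finish the reach unopposed) and capped at 15 Nm. The cap is
applied to the vector magnitude with direction preserved — a safety limit
reads most naturally as a bound on total torque, not per component.

The gain λ is calibrated per subject and mode from the characterization
trials: per-trial *uncapped* peak torque magnitudes are computed at λ = 1,
and λ is set so that the 80th percentile of the peak-torque distribution
(linear interpolation between order statistics) equals 15 Nm — roughly one
trial in five would saturate the limiter. The percentile reading is the
only interpretation that yields a single λ; the quantile convention must
be pinned for the calibration to be exactly reproducible. Calibration
pools trials across directions (one λ per subject, held constant through
training).

## The synthetic learner

The study conditions this package emulates involve human subjects; the
simulator supplies the minimal adapting stand-in that makes the closed
loop testable. The subject plans a minimum-jerk cursor reach and generates
motor commands through an internal affine inverse model `u = A x + b`
(naive default: identity). Under the transformed condition the cursor
shows `G u + c` for a fixed distortion — default `G = R(25°)·diag(1.1,
0.9)`, a smooth invertible remapping whose symmetric part is positive
definite, producing initial errors of several centimeters that differ by
movement direction. White motor noise (default SD 0.3 cm per sample) adds
execution variability, and applied torque displaces the cursor through a
scalar admittance (default 0.08 cm/Nm, a conservative stand-in for limb
compliance: a capped 15 Nm torque displaces the cursor by at most 1.2 cm).

Within a trial the control loop is causal: torque at sample `k` is
computed from the error at sample `k − 1` (one-sample latency at 100 Hz),
and the torque-induced displacement is part of the recorded error at
sample `k`. A divergence guard aborts if the error passes 10³ cm, which
can only happen with pathological admittance/gain combinations.

Between trials the internal map adapts by retention plus a normalized LMS
gradient step on the time-averaged *experienced* error (the error
including torque displacement):

    A ← A₀ + r (A − A₀) − η · mean(ε x_refᵀ) / (L²/2)
    b ← r b − η · mean(ε)

with retention `r = 0.98`, learning rate `η` (default 0.10, per-subject in
cohorts), `A₀ = I` and reach length `L`. The update never consults the
true distortion; it assumes the learner attributes error to its own
commands, which converges because the distortion's symmetric part is
positive definite. This is the standard trial-by-trial linear state-space
adaptation model and produces the exponential error decay the analysis
fits. It is also the mechanism by which augmentation matters: EF/EA
torques enlarge the experienced error, which scales the gradient step.

Protocol (per subject): 30 baseline trials with veridical feedback; 50
intermittent-exposure trials with the distortion on a random 1-in-5 subset
(stratified across directions, so each direction contributes ≥ 2 transformed
trials to characterization); characterization and λ calibration; 70
training trials with the distortion always on and forces per mode. The
learner adapts after every trial, including intermittent ones — as with
human subjects, the sparse transformed trials cause some pre-learning, and
the interleaved veridical trials largely wash it out. Movement-duration
feedback is reported as proper/slow/fast with a ±0.15 s band around
`td` (the band is not prescribed by the task; it is configurable).

Cohorts draw per-subject learning rate (uniform 0.06–0.16), motor noise SD
(uniform 0.2–0.45 cm) and a small random initial-map perturbation
(elementwise SD 0.05), giving the between-subject heterogeneity the group
statistics need. All randomness in a run descends from one seed
(`numpy` `SeedSequence` spawning), so every dataset is exactly
reproducible.

## Analysis

Per-trial performance is the time-averaged error magnitude over `[0, td]`.
The training series is fitted with `y(t) = S + R e^{−t/τ}` (`t` = trial
number) by non-negative least squares: at fixed τ the model is linear in
`(S, R) ≥ 0` and solved exactly by NNLS; τ is scanned on 200 log-spaced
points in `[0.5, 500]` trials and then refined by bounded 1-D minimization
between the neighbouring grid points. The explicit grid keeps the
notoriously ill-identified time constant inspectable (late-training
variability can push fits toward absurdly slow constants; the bounds make
that failure mode visible), while the refinement resolves τ essentially
exactly on clean data. For a constant series `R = 0`, τ is unidentifiable
and is reported at the grid edge with `tau_at_edge = True`. NRMSE is the
RMS residual divided by the range of the fitted series (the most common
normalization; on test data, the range of the training subset).

Cross-validated group fits return `n + 1` fits for `n` subjects: one
pooling all subjects and one per left-out subject, each fit repeated 50
times on random 80 % subsets with the best test-NRMSE repeat retained.
"Change in Error" is the mean of the first five training errors minus the
mean of the last five — a non-parametric per-subject learning measure.

Group comparison runs Shapiro-Wilk per group, a Kruskal-Wallis omnibus
test, and Dunn's rank-based pairwise z tests with Šidák correction
(`p_adj = 1 − (1 − p)^m`); Dunn's test is implemented in-package (with the
standard tie correction) since no installed library provides it, while the
omnibus and normality tests use scipy. Percent differences of group
medians and means accompany every pairwise contrast.

The distribution-shift measure compares early- and late-training error
ensembles (default: first and last 10 training trials; the acceptance
script uses 5 per direction) per direction and component: in each of 50
time bins, the late-minus-early difference in mean error is normalized by
the early SD, and the absolute values are averaged over bins populated by
both ensembles.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale: cohorts
of 7 subjects per group (EF, EA, control) over the full
30 + 50 + 70-trial protocol at 100 Hz, repeated over 10 base seeds in the
closed-loop test; the safety sweep stresses the controllers with 10⁵
adversarial samples up to 10⁶ cm. These sizes exercise every code path
while keeping a full run in tens of seconds. Every stochastic component
takes an explicit seed and is bit-reproducible.

## What the simulator does and does not show

The generator emulates: direction-dependent, time-varying error
distributions under a visuomotor distortion; trial-by-trial error-driven
adaptation with retention; motor noise; compliance to applied torque; and
the full characterize → calibrate → train pipeline. It does not emulate:
muscle-level impedance or co-contraction (the angle-angle remapping task
is specifically one where impedance cannot help), biomechanical joint
limits beyond a generous clip, fatigue, attention, or the possibility that
torque shapes learning through channels other than experienced error.
Passing tests therefore demonstrate the *machinery* — statistics,
controllers, calibration, fitting — on a learner whose ground truth is
known; they do not by themselves establish which augmentation mode best
trains humans, and the simulated group contrasts need not reproduce
human-cohort effect sizes.

## Known limitations

- The Gaussian field assumes symmetric, unimodal error at each instant;
  characterization is frozen after intermittent exposure, so late-training
  error shrinkage is not re-targeted.
- The learner is linear-affine; real adaptation shows savings,
  generalization structure and state-dependent noise this model omits.
- λ calibration assumes the characterization errors are representative of
  training errors; a subject whose errors collapse immediately would be
  over-driven until the cap intervenes.
- The external-data loader maps third-party tables by descriptor; it does
  not guess units or column semantics.
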