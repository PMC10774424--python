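# Methods

This note documents the generative models, the analysis definitions, the
numerical choices, and what the synthetic validation does and does not
establish about real recordings.

## Virtual fish: closed-loop swimming behavior

The behavioral generator emulates a freely swimming 6 dpf larva in a
closed-loop rig where gratings are locked to the body axis. Because the
stimulus frame follows the fish, stimulus direction is defined in the fish
frame and heading changes do not alter it; no visual scene is rendered.
Sign convention, used everywhere in the package: positive angles are
leftward (counter-clockwise) turns, and a leftward stimulus makes positive
turns correct.

**Trial protocol.** 5 s static grating, 10 s motion at 1 cm/s (spatial
period 1 cm), 5 s static; 30 sets, each containing the conditions
{none, forward, backward, left, right} exactly once in per-set randomized
order; tracking at 100 Hz.

**Bout process.** Swim bouts are a renewal process with exponential
inter-bout intervals and a hard 200 ms refractory period. The hazard is
inflated to r/(1 − r·t_ref) so the long-run bout rate equals the nominal
rate exactly; time-varying rates are handled by thinning. Base rates:
0.5 Hz without motion, 1.0 Hz during motion, matching free-swimming
larvae. Each bout deposits its turn angle and a forward displacement
(0.12 cm mean) over a 150 ms raised-cosine ramp in the 100 Hz trace —
enough structure for realistic detection without a hydrodynamic model.

**Turn statistics.** Each bout is a forward swim (angle ~ N(0, 3.5°)) or a
turn (|N(32°, 12°)| with a chosen sign); the turn fraction is 0.4 without
and 0.6 with directional motion. The fish's directional fidelity is set by
`p_correct`, the asymptotic probability that a turn matches the
stimulus; the instantaneous probability is
p_eff(t) = 0.5 + (p_correct − 0.5)·E(t), where the evidence accumulator E
obeys dE/dt = (s − E)/τ_int with s = 1 during motion, solved analytically
phase by phase across the whole session.

τ_int defaults to 0.1 s: with a fast accumulator the session-pooled
proportion correct equals the asymptote to a few tenths of a percentage
point, which is what makes end-to-end parameter recovery well-posed — the
pooled metric is 0.5 + (p − 0.5)·mean(E), and a seconds-scale default
would depress it by several points (mean E over a 10 s window is 0.80 at
τ = 2 s). Slow evidence integration is a regime the simulator exposes
rather than a default: the within-stimulus integration analyses pass
τ_int = 2 s explicitly and verify the rising accuracy curve.

**Rearing and anesthesia conditions.**

| condition | accuracy target | bout rate |
|---|---|---|
| control | 0.967 | 0.5 / 1.0 Hz |
| dark | 0.949, first-trial 0.94 with a 3-trial transient | unchanged |
| strobe | 0.95, same transient shape | unchanged |
| tricaine_reared | washout curve: 0 h → 0.55, 2 h → 0.75, 6 h → 0.89, 24 h → 0.93 (linear interpolation, clamped) | capped at 50% of control |
| acute_tricaine | control target | gain 1 − e^{−t/τ_rec}, τ_rec = 25 min |

Backward-moving gratings use the stimulated bout rate with zero turn bias;
no backward-specific turn statistics are modeled (a guess, labeled as
such — the literature this emulates reports none).

## Bout detection and behavioral metrics

Detection computes angular speed |Δheading|/Δt and translational speed
from frame differences, smooths both with a 30 ms boxcar, thresholds
(80 °/s or 0.4 cm/s), merges epochs closer than 30 ms, drops epochs
shorter than 50 ms, and reads the turn angle as the heading change across
the padded epoch. On default-noise synthetic sessions this matches ground
truth one-to-one within 100 ms at recall = precision = 1.00 and angle
error < 1.2°.

Proportion correct uses motion-phase bouts whose |angle| exceeds the 10°
forward band; forward swims are excluded from the denominator because the
turn distribution has a dominant forward mode at 0° and counting those
as incorrect would bound accuracy far below observed values. Exact-zero
angles are excluded as measure-zero ties. Turn distributions use 5°
left-closed bins over [−180°, 180°); time-resolved accuracy uses 1 s
half-open bins with clock zero at motion onset, and empty bins stay
undefined (NaN), never interpolated. Group summaries are median + IQR
(numpy linear-interpolation quartiles) throughout.

## Synthetic calcium units

Each imaged unit (a cluster of 1–5 similarly tuned neurons) follows a
drive/indicator cascade over 60 s trials (10 s static, 30 s motion at
randomized left/right, 20 s static; 1 Hz frames; 60 trials per 1 h block):

* drive r(t) relaxes toward the unit's amplitude with τ_on during
  preferred-direction motion (both directions for motion-selective,
  negative target for suppressed units) and toward zero with τ_off
  otherwise;
* the indicator impulse response is a unit-gain single exponential with a
  1.8 s constant (a slow GCaMP-like kernel; a config field — at 1 Hz
  sampling a separate rise model is unidentifiable);
* fluorescence = baseline + gain(t)·(kernel ∗ drive) + Gaussian frame
  noise, with an optional small multiplicative flicker on the baseline
  during anesthesia blocks (stimulus-uncorrelated background).

The cascade is integrated **analytically segment by segment** (the drive
is piecewise exponential, so the convolved response is a closed-form sum
of two exponentials per phase); the sampling step only controls gain
evaluation and 1 s frame averaging. This removes discretization error
from the generator, which matters because the kinetics fitter is checked
against it at sub-percent tolerance.

The anesthesia gain is 1 in awake baseline blocks, exactly 0 under
tricaine, and a logistic 1/(1 + e^{−(t − x₀)/k}) in washout time
(minutes). Using the same logistic family the analysis fits makes
recovery-parameter recovery well-posed; robustness to a mismatched
(piecewise-linear) gain is exercised separately through the `gain_fn`
hook. Frame k covers [k, k+1) s, motion starts at trial frame 10, and all
coordinates are 0-based with half-open ROI boxes.

Population defaults: tuning mix 30/30/25/15% left/right/motion/suppressed;
τ_on log-uniform on 0.2–3 s and τ_off log-uniform on 2–20 s (the reported
ranges); recovery midpoints Gaussian with mean 45 min (acute) or 90 min
(lifetime), SD 12 min; 15% of units get amplitudes below the fittable
threshold on purpose.

## Indices

* **C − C₀** per trial: C₀ is the mean of the 10 pre-motion frames,
  subtracted from every frame. No division anywhere — zero baselines are
  valid input by design. The trial scalar averages C − C₀ over the full
  trial by default (a motion-window variant is a config switch).
* **Responsiveness**: per-unit max-absolute normalization across *all*
  trials of the multi-hour experiment (not per block), signs preserved;
  the class of a unit (+1- vs −1-normalized) is the sign of its summed
  trial means. Whether the original procedure rescales increase/decrease
  branches separately is not documented; max-absolute with sign
  preservation is adopted and isolated in one function.
* **DSI**: adjacent left-then-right pairs in schedule order,
  non-conforming adjacencies skipped, paired trials not reused;
  d = r_left − r_right normalized per unit by max |d|. The stimulus
  scheduler guarantees at least one conforming pair per block by
  construction (balanced shuffled pairs).
* **Fittable filter**: strict max C − C₀ > 100 over the whole experiment.

A deliberate consequence of per-unit normalization: in anesthesia blocks
the indices amplify noise (activity is zero, the normalizer is the awake
maximum), so tricaine-block DSI is centred on zero with small magnitude —
the synthetic pipeline reproduces this and the tests assert it.

## Fitting

All fitters are deterministic: 8 fixed initial guesses from data
quantiles, best RSS wins, near-ties broken toward the smaller time
constant (`scipy.optimize.least_squares`, tolerances 1e-15).

* **Exponential bout-rate recovery** r_inf·(1 − e^{−(t−t₀)/τ}), zero
  before t₀; t₀ is a free delay that can be pinned to 0 via argument
  (whether the original fit includes a delay is not documented). Flat or
  all-zero input → `converged=False`, never a fabricated fit.
* **Logistic recovery** A/(1 + e^{−(t−x₀)/k}) with k a *time constant*
  (denominator scale), not a slope parameter. Decreasing-in-time input is
  flagged `"decreasing"` rather than silently fitted. Input series: the
  magnitude of the normalized responsiveness per trial against minutes
  since washout start, tricaine-block trials included as the floor and
  awake baseline excluded; magnitudes let suppressed units recover toward
  1 as well.
* **Onset/offset kinetics** are fitted on preferred-direction
  trial-averaged C − C₀. The onset model is the kernel-convolved,
  frame-bin-averaged closed form c_max·G(t; τ_on, τ_k) + d; the offset
  model is the free two-exponential a·e^{−t/τ_off} + b·e^{−t/τ_k} + d with
  the kernel constant known from the protocol and c_max re-estimated, not
  inherited. The constant d absorbs the shift that baseline subtraction
  introduces when calcium carries over into the pre-motion window. By
  default only preferred trials preceded by a non-preferred trial enter
  the average ("fresh-start" selection), removing carryover from the
  baseline window entirely; units that prefer every trial fall back to
  all trials. Bounds τ_on ∈ [0.05, 30] s, τ_off ∈ [0.1, 60] s; estimates
  at a bound are flagged `"unresolved"`, fitted τ_on below the 1 s frame
  interval is flagged `"sub-frame"` (the generator flags such ground-truth
  parameters too, but the kernel spreads information across frames, so
  sub-frame constants down to ~0.5 s remain recoverable on noiseless
  averages).

The kernel-bias audit (`analysis/06_kernel_bias_audit.py`) is the measured
basis for the fit tolerances: on the τ_on ∈ {0.5, 1, 2, 3} s ×
τ_off ∈ {5, 10, 20} s grid, a naive exponential fit that ignores the
kernel overestimates τ_on by 48–309% and distorts τ_off by up to 74%,
while the kernel-aware fit is accurate to ≤ 0.1%. The pipeline's
noiseless-recovery tests assert 5%; the audited headroom is two orders of
magnitude.

## Statistics

Two-group comparisons: two-sided Kolmogorov–Smirnov (the default across
figure-level comparisons) or Mann–Whitney; omnibus: Kruskal–Wallis.
Effect sizes are absolute differences of group medians in the metric's
own units, never test statistics. No multiple-testing correction is
applied by default, matching the reporting style this mirrors; Bonferroni
is available behind an explicit call. Type-I error of all three tests is
verified to sit in [0.03, 0.07] at α = 0.05 over 2000 null replicates
(the exact KS test is mildly conservative at moderate n — measured, not
assumed).

## Problem sizes used in validation

End-to-end accuracy recovery uses 30 fish × 30 sets per condition on a
left/right-only protocol — the same 60 directional trials per fish as the
full five-condition protocol, at 40% of the simulation cost, since only
directional trials enter the accuracy metric. Bout-rate recovery uses 50
seeds of 90 min acute sessions binned at 2 min. Tuning recovery uses the
full populations (147 acute, 134 lifetime units over 4–5 one-hour
blocks). The recovery-ordering experiment uses 100 replicates of 6-unit
cohorts per arm — small per-replicate cohorts make the ordering check a
property of the method, not of a single large sample.

## What passing tests do and do not show

The generators produce: renewal-process bouts with stimulus-conditioned
turn bias, smooth bout waveforms, Gaussian tracking noise; linear
drive/kernel calcium dynamics with Gaussian frame noise and an exactly
multiplicative anesthesia gain. They do not produce: kinematic bout-type
diversity (scoots vs J-turns), wall interactions, posture loss,
photobleaching, z-drift, motion artifacts, spiking nonlinearities, or
indicator saturation. Recovery of generator parameters therefore
validates the *estimators and their conventions* (no sign flips, no
normalization errors, honest convergence flags, quantified kernel bias) —
it does not validate the biological realism of the generative
assumptions, and real-data performance will degrade with whatever of the
above a recording contains.

## Known limitations

* The bout detector's thresholds are tuned to the generator's SNR regime;
  real tracking with different noise would need threshold re-selection.
* The logistic recovery fit assumes a monotone recovery; non-monotone
  recoveries (e.g. transient rebound) are flagged as failures rather than
  modeled.
* DSI pairing consumes only left-then-right adjacencies; schedules
  without balanced pairs lose efficiency (the synthetic scheduler
  guarantees them, arbitrary real schedules may not).
* The accuracy washout curve interpolates linearly between four anchors;
  intermediate-washout behavior between anchors is an assumption, not a
  measurement.
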