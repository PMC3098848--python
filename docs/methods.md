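# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Point-light figures

Generated figures are hierarchically articulated: two-segment limb
pendulums swing about shoulder/hip pivots with sinusoidal joint-angle
profiles (swing and distal flexion each have amplitude, phase, mean and an
integer cycle frequency), while the trunk dots bob and sway; an optional
constant translation produces locomotion. The 12 dots are head, torso,
shoulders, elbows, wrists, hips and ankles (knees are folded into the
two-segment leg so the canonical 12-dot budget covers full arm
articulation). Coordinates are degrees of visual angle, x rightward, y
upward, origin at fixation.

Two stimulus constraints are enforced on every generated sequence: mean
per-dot speed is normalized to exactly 4°/s (computed on the discretely
sampled frames, so the contract is exact for the emitted sequence), and the
space-time bounding box must fit the 7° figure window. These constraints
are not jointly satisfiable for arbitrary parameters — a barely-moving
figure rescaled to 4°/s overflows the window — so such parameter sets raise
an error instead of silently violating a constraint; a fully static figure
(all amplitudes zero) skips speed normalization. All 14 named presets
satisfy both constraints at every start phase.

The `seed` of `generate_action` selects a random start phase within the
action cycle, giving distinct exemplars of one action; generation is
bit-reproducible given (params, seed). Sequences default to 20 frames at
50 ms (1 s), the timing used across all three experiment designs.

## Stimulus transforms

*Scrambling* draws first-frame positions uniformly within the display
window and re-applies the source's per-dot displacements:
S_i(t) = S_i(1) + (B_i(t) − B_i(1)). *Perturbation* is the linear morph
P_i(t) = (1−λ)B_i(t) + λS_i(t), equivalently a per-dot constant translation
λ·offset_i; both therefore preserve per-dot velocities exactly, and motion
energy is invariant across morph levels of one action (asserted in tests).

*Noise masking* jitters the figure by a uniform draw within a disc of
radius 1.4° (the trial-to-trial location variation; the distribution is the
package's choice, bounded and isotropic), then adds noise dots that replay
the displacement trajectory of a uniformly chosen figure dot from a uniform
start position in the 11° window. Noise positions wrap toroidally at the
window edge (keeps noise density constant; edge behaviour is otherwise
unconstrained), trajectories are copied without temporal phase offset by
default (simplest reading; an offset option exists), and dot order is
shuffled so the figure cannot be identified by index. The returned object
retains the figure indices as ground truth for tests; a real display would
discard them.

*Motion energy* has two non-identical definitions, both provided: summed
absolute direction change of each dot's displacement vector (wrapped to
(−180°, 180°]; steps adjacent to a zero displacement contribute nothing),
and summed path excursion. Angular deviation is the default; neither is
treated as ground truth.

## Staircase

Two-up/one-down with the published protocol constants: start 20 noise dots,
±6 until 12 reversals are recorded, ±3 thereafter, stop at 16 reversals,
threshold = mean of the last six reversal levels, floor at 0. "Up" raises
the noise count (harder) after two consecutive correct responses — the
orientation that makes the rule converge on P(correct) = √½ ≈ 70.7%.

Bookkeeping conventions (the protocol description leaves them open):

* A reversal is valued at the level of the trial on which the movement
  direction changed — the local extremum of the track.
* On a movement, the reversal is recorded first and the step size is then
  chosen from the updated reversal count, so the movement that records the
  12th reversal already moves by the small step. This ordering is what
  reproduces the exact hand-traceable reversal schedule of a scripted
  correct-correct-error cycle (tail …26, 20, 23, 20, 23, 20 → threshold
  22.0), which the tests pin down.
* The consecutive-correct counter resets on every level movement.
* A 400-trial safety cap ends runs that never accumulate 16 reversals
  (e.g. an error-free observer).

## Simulated observers

Observers are parametric response models, not fits to any participant's
data. Detection uses a Weibull psychometric
P(correct|n) = ½ + (½ − lapse)·exp(−(n/α)^β); discrimination draws a noisy
internal coherence with mean gain·(1−λ)^γ per sequence and picks the larger
sample (γ>1 makes equal 15-point perturbation steps progressively harder,
matching the declining accuracy profile of the paired design); the
categorization observer is equal-variance Gaussian SDT with evidence means
0 / d′ / f·d′ for scrambled / biological / intermediate stimuli and a fixed
criterion. Per-trial randomness comes from counter-keyed streams
(seed, task, trial index), so reordering trials never changes a draw.

Group presets place the detection 70.7% point at the anchor thresholds
(controls ≈ 56, patients ≈ 41 noise dots, β=2, lapse=.01), set d′ to the
anchor sensitivities (3.82 / 2.54) and model the patient discrimination
deficit by reduced gain (an alternative "compressive" preset, in which
perturbed sequences still look largely biological, is included as the
second candidate mechanism). The anchor group-mean rates are not jointly
consistent with a single equal-variance observer (a mean of individual d′
values is not the d′ of the mean rates), so the criterion is anchored on
the hit rate (control c = 1.676 → H=.984, F≈.047; patient c = 0.933 →
H=.946, F≈.175). This preserves the qualitative orderings — patient d′
lower, patient false alarms and intermediate-"biological" rates higher
(≈19% vs ≈5%) — while keeping false-alarm magnitudes below the anchor
means; anchoring on false alarms instead would push the control hit rate to
≈.9985 and visibly bias d′ recovery under the log-linear correction.
Cohort samplers add between-observer spread (log-normal α, SD 0.35;
normal d′, SD 0.8) of the same order as the anchors' group SDs.

## Behavioural statistics

d′ = z(H) − z(F) with c = −(z(H)+z(F))/2; the log-linear correction
((x+0.5)/(n+1)) is the default because near-ceiling hit rates make some
convention mandatory; uncorrected rates of 0 or 1 raise an error naming the
correction. The above-chance criterion is the smallest k with exact
P(X ≥ k | n, p0) < α. Per-activity accuracy pools all perturbation pairings
except the most extreme (45% vs 60%), where performance is at chance for
everyone. Standard tests are the textbook forms: pooled-variance t, Pearson
r, Pearson chi-square without continuity correction, and pooled-SD Cohen's
d recovered from summary statistics (SD = SE·√n) — an approximation when
only summaries are available, and about 0.71 rather than 0.75 for the
archived false-alarm summary, since the individual data behind the latter
are not recoverable. Likewise the archived chi-square of 4.41 for the
8/12-vs-5/15 first-two-trials split is not reproduced by the textbook
statistic (≈2.97); the package implements the textbook statistic and
records the discrepancy rather than reconciling it.

## Experiment designs

Exp 1: 2IFC, signal interval randomized per trial, noise level from the
staircase, 24 trialwise-cycled actions. Exp 2: 4 pairings × 40 trials,
10 activities cycled evenly within pairing, side of the less-perturbed
sequence randomized; how activities were balanced across trials is not
specified in the source protocol, so even cycling is the package's choice.
Exp 3: 9 runs × 24 trials (8 per class, shuffled per run with per-run
seeds); d′ uses biological vs fully-scrambled trials only; "biological"
responses to the intermediate class are reported as a separate rate, never
scored as errors. The intermediate level is stored as 0.375 (midway between
the 30% and 45% morphs) and labelled "37%". Trial logs carry stimulus
provenance (action, seed, λ or noise count, interval/side) so any trial can
be re-rendered exactly; rendering is on demand to keep large cohorts cheap.

## BOLD simulation and ROI analysis

The lattice defaults to 20×20×10 voxels with one ellipsoidal responsive
region of ~72 voxels (inside the 15–174 range of observed region sizes).
Signals are built from a canonical double-gamma HRF (peak 6 s, undershoot
16 s, ratio 1:6) convolved with stimulus boxcars on a 0.1 s grid, sampled
at TR = 2 s, and normalized so an isolated event (or block) peaks at 1.0 on
the TR grid — amplitudes are therefore peak percent signal changes. Noise
is AR(1) (coefficient 0.3) plus white noise of 0.5% SD about a baseline of
100, representing the residual noise of a preprocessed (smoothed,
detrended) series; preprocessing itself is out of scope.

The localizer is 7 cycles of 14 s biological / 14 s scrambled blocks with a
14 s fixation rest per cycle and an 8 s lead-in (316 s scan); rest blocks
provide the baseline and decorrelate the condition regressors. The event
design uses 1 s stimuli at a constant 11 s ISI. Event runs default to
*balanced* per-category counts (8 hits, 4 correct rejections, 4 false
alarms, 8 intermediate per 24-trial run): response-contingent designs
built from a behavioural trial log (`EventDesign.from_trial_log`, which
also labels misses) are the realistic pathway, but a control-like observer
produces only ~3 false alarms per session, too few for a stable
event-related average, so the group-pattern analyses use balanced designs
to test the amplitude-map → analysis chain directly.

GLM: voxelwise OLS with HRF-convolved regressors and one intercept per run;
two-sided p from the t distribution (exactly calibrated under white noise;
mild AR(1) inflates tails slightly, which the FDR null-calibration check
absorbs). ROI: Benjamini–Hochberg step-up at q<.05 over all voxels, falling
back to uncorrected p<.003 when empty, then the largest 6-connected
component (ties broken by higher mean |t|); an empty fallback is reported
as "not localizable". Event-related averages are computed on the ROI-mean
series in percent-of-run-mean units; the peak percent change is the
post-onset maximum within a 10 s window (HRF peak latency, before the next
trial's cue) minus the single onset-sample value, taken from the measured
average, never from a fitted response. Group amplitude maps encode the two
qualitative regimes: percept-contingent (hit .55, false alarm .50, correct
rejection .25, intermediate .35) and undifferentiated (all .40, near the
event-related average amplitude observed in patient cohorts).

## What the synthetic data do and do not show

The generators emulate the *structure* of the study — stimulus geometry and
algebra, adaptive and constant-stimuli designs, SDT behaviour with
group-dependent parameters, response-contingent BOLD amplitudes with
realistic timing — under clean parametric assumptions: stationary
observers with no learning, lapse-free discrimination, Gaussian evidence,
spatially homogeneous noise, no scanner drift or motion. Passing tests
therefore validate the procedures (staircase convergence and threshold
recovery, exact morph algebra, d′ estimation, FDR calibration, ROI
recovery, pattern classification), not any claim about real observers or
real cortex; the preset calibration anchors are documentation of the
simulated conditions, not reproductions of empirical group data.

## Problem sizes

Default analysis sizes were chosen so every check runs comfortably on a
single CPU: 500 staircases for convergence properties, 1000 sessions per
generating d′ for recovery, 100 simulated scans for FDR calibration, and
20 seeds × (1 localizer + 4 event runs) for the end-to-end imaging
pattern check.
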