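# Methods

This note documents the models, numerical choices and limitations behind
`gart`, an offline toolkit for gaze-based attention-refocusing experiments:
a continuous performance task (CPT) performed in a virtual seminar room
while alternating three-minute distractor (DP) and non-distractor (NDP)
phases run, under three counterbalanced feedback conditions (real gaze-
contingent feedback, delayed sham feedback, no feedback), with concurrent
eye tracking (~50 Hz), EEG (500 Hz, 24 channels), head tracking (~90 Hz)
and experience sampling.

## Session model

All streams of one task block share a single clock in seconds with t = 0 at
block start; every analysis window is half-open `[start, end)`, so slicing
a stream by the phases of a schedule partitions its samples exactly and
per-phase counts always sum to block totals. Streams are never resampled
implicitly. Units: seconds, meters, microvolts; oculomotor outputs in
degrees. The standard block is six alternating phases of 180 s (18 min).

## CPT engine

Letters appear for 100 ms with a 1100 ms inter-stimulus interval, 900
trials per block. A trial is a *target* when a 'K' follows an 'A'. Because
targets are defined on letter transitions while proportions are stated over
trials, the generator classifies each trial after the first by its
(previous, current) letter pair; trial 0 is an unclassifiable "opener" and
the 30% target / 50%-of-the-rest pseudo-target composition applies to the
899 classifiable trials (270 targets, 315 pseudo-targets, 314 neutral
transitions; counts rounded half-up).

*Pseudo-target definition.* A pseudo-target is any non-target transition
containing at least one of {A, K}. The narrower reading "exactly one of
{A, K}" would make the standard composition infeasible: every target
needs a preceding transition ending in 'A' and a following transition
starting with 'K' — both necessarily containing a target letter — and
forbidding the shared (K, A) transition would require at least two
pseudo-targets per target (≥ 538, while only 315 exist). Admitting
(K, A), (A, A) and (K, K) as pseudo-targets makes the composition exactly
realizable; the generator builds the stream from neutral-letter runs and
A/K runs so that targets can never arise accidentally, and a test re-derives
all class counts with an independent classifier.

*Scoring.* Each keypress is assigned to the most recent stimulus onset
within the response window; the window defaults to one stimulus-onset
asynchrony (1.2 s), a conventional choice since no explicit bound is
specified for the paradigm, and is configurable. Only the first response
per trial counts. Anticipations are not excluded by default.

## Gaze states and dwell

The scene is reduced to proxy volumes: one canvas box and box/sphere
colliders for distractors (auditory distractors get generous boxes standing
in for sound-source regions). A gaze sample is a ray; the nearest
intersected *active* collider decides among `task_focus`,
`distractor_focus` and `gaze_wandering`; invalid samples (blinks) form
their own state. Exact intersection ties are broken canvas-first, which is
conservative against false inattention. Distractor colliders are hittable
from their scheduled onset for a 3 s linger window — the animation
durations of the original assets are not published, and 3 s is a plausible
event length; it is configurable.

Dwell percentages are taken over total block duration *including* invalid
time (whether the original percentages use total or valid time is not
documented; this choice is exposed through the interval list, from which a
valid-time normalization is a one-line change). The distractibility score
is (distractor-focus % + gaze-wandering %) / task-focus %; it is undefined
(an error) when task focus is zero.

Each DP schedules floor(180/30) = 6 distractors at exact 30 s spacing,
drawn without replacement from the 18 + 18 + 18
visual/auditory/audiovisual pool.

## Feedback controller

A deterministic state machine over the gaze-state stream. Two timers
accumulate while no event is active: off-canvas dwell (any valid non-canvas
state) and distractor dwell (distractor fixation only; it resets when the
gaze moves elsewhere). Registration occurs at the first sample whose
accumulated dwell strictly exceeds 2 s (off-canvas) or 0.5 s (distractor).
Real mode fires immediately at registration; if an event is active or the
5 s refractory period is running, the pending registration fires at the
first admissible sample provided the timers were not reset in between (on
an adversarial trace that re-triggers instantly after every offset this
yields a minimum inter-onset gap of max-duration + refractory = 7 s). Sham
mode schedules the onset at registration + U(20, 30) s and fires regardless
of the momentary gaze state — the delay exists precisely to decouple
feedback from behavior; at most one sham is pending, and registrations
arriving while one waits are absorbed (so sham frequency matches real
frequency only when inattention episodes are spaced beyond the maximum
delay, which the tests make explicit). Events end at the first task-focus
sample or after 2 s; the visual envelope ramps linearly to 35% screen
coverage over 0.5 s. Blink samples freeze both timers — a blink neither
counts as inattention nor proves restored attention.

## Oculomotor pipeline

Preprocessing interpolates per-eye validity gaps of at most 75 ms linearly
on direction components (renormalized), fills one-eye loss from the other
eye, averages the eyes, and reports residual data loss. Angular velocity is
the arc between consecutive direction vectors over elapsed time (origin
motion ignored — head-relative gaze), smoothed with a second-order
Savitzky-Golay filter; the window defaults to 5 samples (~100 ms at 50 Hz),
a value not fixed by the original description and therefore exposed.

The saccade threshold is data-driven: starting from 100 deg/s, iterate
PT ← mean + 6·SD of the sub-threshold samples until the change is below
1 deg/s. The iteration runs on the *raw* (unsmoothed) velocities: at 50 Hz
the smoothing kernel smears each saccade over several samples, and those
shoulder velocities inflate the sub-threshold SD enough to destabilize the
fixed point, while the raw trace keeps fixation noise and saccade peaks
cleanly separated. Detection then applies the converged threshold to the
smoothed trace; supra-threshold runs become saccades with onset/offset
refined to the adjacent velocity minima, and inter-saccade spans become
fixation candidates. Candidates shorter than 60 ms are discarded, then
fixations separated by at most 40 ms are merged (in that order). A merge
can swallow the micro-event between the pair; saccades lying wholly inside
a merged fixation are dropped so saccades and fixations never overlap.
Saccade amplitude is the angle between the mean directions immediately
before and after the event.

Microsaccade detection is out of scope: 50 Hz sampling is far below what
that requires.

## EEG theta/beta ratio

Per channel: linear detrend, then zero-phase 4th-order Butterworth low-pass
at 35 Hz (detrending first keeps the ramp out of the filter's edge
transients). Each condition × phase subset is cut into non-overlapping 5 s
epochs fully inside a phase; "baseline correction" for a free-running 5 s
segment is read as per-epoch mean subtraction. Artifact screening is a
documented amplitude threshold (reject an epoch if any channel exceeds
100 µV after mean removal): the original expert-guided ICA plus visual
component rejection is intentionally out of scope because it is not
deterministic or reproducible without a human rater.

Time-frequency power uses a complex Morlet continuous wavelet transform
(PyWavelets `cmor1.82-1.0`, equivalent to ~6 cycles; the wavelet family and
width are not fixed by the original description and are configurable) on
85 log-spaced frequencies from 0.1 to 35 Hz, evaluated on a 4 ms time
grid. Power is divided by the wavelet scale at each frequency so that
equal-amplitude sinusoids yield comparable power across the log grid
(verified flat within ~2%); band means are then taken over theta (4–7 Hz)
and beta (13–30 Hz) and t ∈ [0.5, 4.5] s, averaged across epochs, and the
TBR is theta/beta at electrode Fz. The ratio is exactly invariant to any
common gain on the raw signal.

## Head actigraphy

The ~90 Hz HMD position trace is block-averaged by the integer factor
nearest rate/10 (boxcar anti-aliasing without edge transients), and the
summary is the mean Euclidean distance between consecutive downsampled
positions — per step at ~10 Hz, the reading adopted for the ambiguous
"mean distances". The metric is invariant to constant offsets and global
rotations.

## Statistical battery

Mixed ANOVAs use the univariate sums-of-squares decomposition with subjects
nested in groups: 2 × 3 × 2 (Group × Feedback Condition × Phase) for the
per-phase measures and 2 × 3 for dwell and experience-sampling scores.
Neither pingouin (one within factor) nor statsmodels' AnovaRM (no between
factor) covers the three-way mixed design, so the decomposition is
implemented here; the 2 × 3 path is cross-checked against
`pingouin.mixed_anova` and the 2 × 3 × 2 path against a naive loop-based
sums-of-squares oracle in the tests. Sphericity epsilons (Greenhouse-
Geisser and Huynh-Feldt) come from orthonormal-contrast covariance
matrices; following the ε > 0.75 convention, HF is applied above that
value and GG below it, for within effects with more than two levels (the
published description's "Huynh field" is read as Huynh-Feldt). Effect
sizes are partial η². Post-hocs are Bonferroni-adjusted pairwise t-tests;
correlation matrices (Pearson or Spearman) carry Benjamini-Hochberg
adjusted p-values computed across the off-diagonal tests of one matrix.
All tests are two-sided at α = 0.05.

## Synthetic participant simulator

The generative model is a semi-Markov process over latent attention states
with exponential holding times (sampled event-driven, with thinning for the
time-varying hazards):

| parameter | ADHD | HC | role |
|---|---|---|---|
| distraction_hazard (1/s) | 0.50 | 0.30 | leave toward an animating distractor |
| wander_hazard (1/s) | 0.050 | 0.024 | leave into mind wandering |
| refocus_hazard (1/s) | 0.50 | 0.50 | return to task |
| distractor_disengage | 1.0 | 2.2 | disengagement speed-up while distracted |
| dp_wander_boost | 1.3 | 1.3 | wander hazard multiplier during DP |
| rt_median (ms) | 458 | 428 | log-normal RT location |
| omission p (on/off task) | .004 / .075 | .002 / .025 | state-dependent misses |
| commission p | .0019 | .0014 | false alarms per non-target |
| head_step_sigma (m) | 3.9e-4 | 1.7e-4 | 90 Hz random-walk step |
| blink_rate (1/s) | 0.155 | 0.155 | Poisson blink overlay |

Distraction is possible only while a distractor animates (onset + 3 s), so
distractor dwell concentrates in DP by construction; wandering is mildly
elevated during DP, producing the DP > NDP omission direction. The healthy
profile differs mainly in lower leave hazards and faster disengagement from
distractors (the published group contrast is consistent with similar
orienting but faster disengagement). These defaults were calibrated once so
that full-length simulated 18+18 cohorts approximate the reference group
means of the paradigm (per-block omissions ≈ 2.4 vs 0.8, mean RT ≈ 477 vs
437 ms, distractor dwell ≈ 1.6% vs 0.8%, task focus ≈ 86% vs 91%, head
step ≈ 1.75 vs 0.84 mm, data loss ≈ 2.6%); they were not revisited after
the tests were written. The head-movement reference means carry no unit in
the source material; the simulator targets millimetres per 10 Hz step,
which is a plausible magnitude for seated head sway, and only the group
*ordering* is treated as a checkable claim.

Feedback coupling: active feedback multiplies the refocus hazard by
`feedback_refocus_boost`. The default is 1 — no immediate effect of the
feedback was demonstrated, so the boost is a mechanism knob for testing,
not a claim. For boost ≠ 1 the coupling is approximated inside the episode
sampler (the boost window opens at the controller's trigger latency after
the episode starts and lasts one maximum event duration); the feedback
events actually *recorded* in a simulated block always come from running
the real controller on the rendered, ray-classified gaze stream.

Rendering: on-task gaze fixates jittered canvas points (0.1° component
noise) with Poisson relocations at 1.2/s (ground-truth saccades);
distracted gaze fixates the animating distractor's collider; wandering
points into an upward cone that intersects nothing; blinks are invalid
samples. EEG is 1/f background (8 µV) plus theta (5.5 Hz) and beta
(18.5 Hz) oscillations with a 1.2% theta amplitude raise during DP and
rare 400 µV spikes to exercise epoch rejection. Head position is a
mean-reverting (AR ρ = 0.995) random walk. Responses follow the
state-dependent probabilities above with log-normal RTs (σ = 0.18,
off-task responses 15% slower).

What the simulator does *not* emulate: smooth pursuit, vergence and depth,
pupil dynamics, realistic EEG topography or artifact morphology,
oculomotor main-sequence kinematics within a saccade, or any cognitive
strategy. Passing tests therefore demonstrate that the pipeline recovers
the statistical structure it assumes from data of that structure — not
that real recordings satisfy those assumptions.

## Problem sizes and reproducibility

Deterministic checks (controller latencies, detector filters, schedule
arithmetic) run at full fidelity. Replicated cohort checks (group-ordering
recovery, null behaviour of the Feedback Condition test) use 18+18
participants with shortened blocks — one DP/NDP cycle of 90 s each — and
10 replicates; the orderings under test are scale-free, and the shortened
blocks keep the whole battery at desk scale. Every random quantity flows
from a single seed through `numpy.random.SeedSequence`-style derivation,
so reruns are bit-identical.

Known limitations: the adaptive-threshold literature family has several
published variants and the exact original variant is not recoverable from
the description this toolkit follows; the response window, dwell
denominator and artifact criteria are documented choices exposed as
configuration; and the simulator's profiles are calibrated to printed
group means, not fitted to raw data.
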